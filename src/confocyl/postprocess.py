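"""Post-processing of simulated confocal scans.

The evaluation pipeline applied to raw detected-fraction images, in the
fixed order: line-wise background subtraction, moving-average smoothing,
normalisation, then (display only) cubic upscaling and logarithmic view.
Each step returns a new :class:`~confocyl.scan.ScanImage`; none mutate
their input.
"""

from __future__ import annotations

import numpy as np
import scipy.interpolate

from .scan import ScanImage

__all__ = [
    "normalise",
    "moving_average",
    "upscale_cubic",
    "subtract_background_lines",
    "log_view",
]


def _copy_with(image: ScanImage, data, axis_y=None, axis_z=None) -> ScanImage:
    return ScanImage(
        data=np.asarray(data, dtype=float),
        axis_y=image.axis_y if axis_y is None else axis_y,
        axis_z=image.axis_z if axis_z is None else axis_z,
        meta=dict(image.meta),
    )


def normalise(
    image: ScanImage,
    reference: str = "max",
    region: tuple[slice, slice] | None = None,
) -> ScanImage:
    """Scale so that the reference maximum equals one.

    ``reference="max"`` uses the global maximum; ``reference="region"``
    uses the maximum inside ``region`` (a pair of slices), e.g. the first
    cylinder surface when strong substrate reflexes would otherwise
    dominate the scale.
    """
    if reference == "max":
        ref = image.data.max()
    elif reference == "region":
        if region is None:
            raise ValueError("region normalisation requires a region")
        ref = image.data[region].max()
    else:
        raise ValueError("reference must be 'max' or 'region'")
    if ref <= 0:
        raise ValueError("cannot normalise an image with no signal")
    return _copy_with(image, image.data / ref)


def moving_average(image: ScanImage, width: int = 5) -> ScanImage:
    """Per-row moving average along z with an odd window width.

    Edges are handled by shrinking the window, so a constant image is a
    fixed point and an interior impulse spreads to ``width`` pixels of
    value ``1/width``.
    """
    if width % 2 == 0 or width < 1:
        raise ValueError("width must be odd and >= 1")
    if width == 1:
        return _copy_with(image, image.data.copy())
    half = width // 2
    n = image.data.shape[1]
    csum = np.cumsum(np.pad(image.data, ((0, 0), (1, 0))), axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    out = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return _copy_with(image, out)


def upscale_cubic(image: ScanImage, factor: int = 2) -> ScanImage:
    """Refine both axes by an integer factor with cubic interpolation.

    Output dimensions are ``(n - 1) * factor + 1`` per axis; interpolated
    values are clipped at zero so no negative intensities appear.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return _copy_with(image, image.data.copy())
    new_y = np.linspace(
        image.axis_y[0], image.axis_y[-1], (image.axis_y.size - 1) * factor + 1
    )
    new_z = np.linspace(
        image.axis_z[0], image.axis_z[-1], (image.axis_z.size - 1) * factor + 1
    )
    ky = min(3, image.axis_y.size - 1)
    kz = min(3, image.axis_z.size - 1)
    spline = scipy.interpolate.RectBivariateSpline(
        image.axis_y, image.axis_z, image.data, kx=ky, ky=kz
    )
    out = np.clip(spline(new_y, new_z), 0.0, None)
    return _copy_with(image, out, axis_y=new_y, axis_z=new_z)


def subtract_background_lines(
    image: ScanImage, estimator: str = "percentile", percentile: float = 5.0
) -> ScanImage:
    """Subtract a per-row background estimate and clip at zero.

    ``estimator="min"`` removes the row minimum exactly;
    ``estimator="percentile"`` (default, 5th percentile) is robust when a
    row contains sparse bright reflexes.
    """
    if estimator == "min":
        bg = image.data.min(axis=1, keepdims=True)
    elif estimator == "percentile":
        bg = np.percentile(image.data, percentile, axis=1, keepdims=True)
    else:
        raise ValueError("estimator must be 'min' or 'percentile'")
    return _copy_with(image, np.clip(image.data - bg, 0.0, None))


def log_view(
    image: ScanImage, floor: float = 1e-4, gain: float = 1.0, normref: float | None = None
) -> np.ndarray:
    """Logarithmic display grid ``log10(max(gain * data / normref, floor))``.

    ``gain`` mirrors the empirical display factors used when comparing
    simulations with attenuated measurements; it is display-only and never
    part of any quantitative result.  Returns a plain array (a view for
    plotting, not a ScanImage).
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    ref = image.data.max() if normref is None else normref
    if ref <= 0:
        raise ValueError("cannot form a log view of an empty image")
    return np.log10(np.maximum(gain * image.data / ref, floor))
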
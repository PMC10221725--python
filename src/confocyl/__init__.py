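"""confocyl: confocal laser scanning microscope image formation for
multi-cylinder phantoms.

Two complementary engines compute reflectance confocal images of parallel
dielectric cylinders: an exact Maxwell series solution for a single
cylinder (2D, both polarisations) and a ray-based Monte Carlo with a thin
lens, ABCD detection mapping and a pinhole, which scales to multi-cylinder
scenes.  Phantom generation and the standard post-processing pipeline are
included.
"""

from importlib import resources

from .maxwell import (
    ConfocalField,
    confocal_amplitude,
    confocal_image,
    radius_averaged_image,
)
from .mc import (
    DetectionRecord,
    OpticalSystem,
    Photon,
    fresnel_interact,
    fresnel_reflectance,
    intersect_ray_cylinder,
    launch_photon,
    lens_diameter,
    simulate_pixel,
    trace,
)
from .phantom import (
    Cylinder,
    Phantom,
    PhantomValidationError,
    generate_phantom,
    read_phantom,
    single_cylinder_phantom,
    tilt_phantom,
    write_phantom,
)
from .postprocess import (
    log_view,
    moving_average,
    normalise,
    subtract_background_lines,
    upscale_cubic,
)
from .scan import AxialProfile, ScanImage, axial_reflex_positions, simulate_scan
from .scattering import (
    CylinderScatteringSolution,
    amplitude,
    forward_backward_orders,
    scattering_efficiency,
    solve_cylinder,
)

__version__ = "0.1.0"


def fixture_phantom(name: str):
    """Load one of the frozen example phantoms shipped with the package.

    ``name`` is ``"r10"`` (12 cylinders of radius 10 um) or ``"r5"``
    (51 cylinders of radius 5 um).  These are reproducible layouts from
    :func:`generate_phantom` at fixed seeds, not the (unpublished)
    coordinates of any physical phantom.
    """
    files = {"r10": "phantom_r10_12cyl.json", "r5": "phantom_r5_51cyl.json"}
    if name not in files:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(files)}")
    with resources.as_file(
        resources.files("confocyl.data").joinpath(files[name])
    ) as path:
        return read_phantom(path)
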
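"""Scan-image persistence: float32 TIFF with a JSON axis/metadata sidecar.

The TIFF holds the raw data grid; the sidecar (``<stem>.json`` next to it)
holds the axis vectors and simulation metadata, so a written scan can be
reproduced bit-for-bit from its sidecar alone.  A CSV export (one row per
y line, axes in the header) is provided for spreadsheet inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .scan import ScanImage

__all__ = ["write_image", "read_image", "write_csv"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_image(image: ScanImage, path: str | Path) -> None:
    """Write a float32 TIFF and its JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, image.data.astype(np.float32))
    _sidecar(path).write_text(
        json.dumps(
            {
                "axis_y_um": image.axis_y.tolist(),
                "axis_z_um": image.axis_z.tolist(),
                "meta": image.meta,
            },
            indent=1,
        )
    )


def read_image(path: str | Path) -> ScanImage:
    """Read a TIFF + sidecar pair written by :func:`write_image`."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing axis sidecar {side}")
    doc = json.loads(side.read_text())
    data = tifffile.imread(path).astype(float)
    return ScanImage(
        data=data,
        axis_y=np.asarray(doc["axis_y_um"], dtype=float),
        axis_z=np.asarray(doc["axis_z_um"], dtype=float),
        meta=doc.get("meta", {}),
    )


def write_csv(image: ScanImage, path: str | Path) -> None:
    """CSV export: first row z axis, first column y axis."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("y_um\\z_um," + ",".join(f"{z:.9g}" for z in image.axis_z) + "\n")
        for y, row in zip(image.axis_y, image.data):
            fh.write(f"{y:.9g}," + ",".join(f"{v:.9g}" for v in row) + "\n")
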
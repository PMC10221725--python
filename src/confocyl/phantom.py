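"""Multi-cylinder phantom geometries: generation, transforms and JSON I/O.

A phantom is a set of parallel dielectric cylinders (axes along x) placed in
a rectangular slab cross-section in the y-z plane, mimicking two-photon
polymerised scattering phantoms: a 200 x 200 um^2 slab randomly filled with
non-overlapping cylinders of a single radius to roughly 10 % area fill.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Cylinder",
    "Phantom",
    "PhantomValidationError",
    "generate_phantom",
    "tilt_phantom",
    "read_phantom",
    "write_phantom",
]

SCHEMA_VERSION = 1


class PhantomValidationError(ValueError):
    """Raised when a phantom description violates a geometric invariant."""


@dataclass(frozen=True)
class Cylinder:
    """Infinite cylinder along x with centre (cy, cz) in the y-z plane, um."""

    center_y: float
    center_z: float
    radius: float
    n_cyl: float

    def __post_init__(self):
        if not self.radius > 0:
            raise PhantomValidationError(f"radius must be positive, got {self.radius}")
        if not self.n_cyl > 0:
            raise PhantomValidationError(f"n_cyl must be positive, got {self.n_cyl}")


@dataclass(frozen=True)
class Phantom:
    """Parallel-cylinder scene.

    The slab cross-section spans ``[-slab_y/2, slab_y/2] x [-slab_z/2,
    slab_z/2]`` centred at the origin; ``length_x`` is informational (the
    cylinders are treated as infinite along x and clipped by scene bounds).
    Volume scattering and absorption coefficients are accepted for
    completeness but must be zero: the media are clear resins and the model
    is surface-only.
    """

    cylinders: tuple[Cylinder, ...]
    slab_y: float = 200.0
    slab_z: float = 200.0
    length_x: float = 200.0
    n_surround: float = 1.0
    seed: int | None = None
    achieved_fill: float | None = None
    mu_s: float = 0.0
    mu_a: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "cylinders", tuple(self.cylinders))
        if self.mu_s != 0.0 or self.mu_a != 0.0:
            raise PhantomValidationError(
                "volume scattering/absorption not supported: mu_s and mu_a must be 0"
            )
        validate_geometry(self)

    @property
    def fill_fraction(self) -> float:
        """Area fraction of the slab cross-section occupied by cylinders."""
        area = sum(np.pi * c.radius**2 for c in self.cylinders)
        return area / (self.slab_y * self.slab_z)


def validate_geometry(phantom: Phantom, margin: float = 0.0) -> None:
    """Check containment and pairwise non-overlap; raise naming offenders."""
    hy, hz = phantom.slab_y / 2.0, phantom.slab_z / 2.0
    for i, c in enumerate(phantom.cylinders):
        if (
            abs(c.center_y) + c.radius > hy + 1e-9
            or abs(c.center_z) + c.radius > hz + 1e-9
        ):
            raise PhantomValidationError(
                f"cylinder {i} at ({c.center_y}, {c.center_z}) r={c.radius} "
                "extends outside the slab cross-section"
            )
    cyls = phantom.cylinders
    for i in range(len(cyls)):
        for j in range(i + 1, len(cyls)):
            d = np.hypot(
                cyls[i].center_y - cyls[j].center_y,
                cyls[i].center_z - cyls[j].center_z,
            )
            if d < cyls[i].radius + cyls[j].radius + margin - 1e-9:
                raise PhantomValidationError(
                    f"cylinders {i} and {j} overlap (centre distance {d:.6g} um "
                    f"< {cyls[i].radius + cyls[j].radius + margin:.6g} um)"
                )


def generate_phantom(
    radius: float,
    target_fill: float = 0.10,
    n_cyl: float = 1.6285,
    n_surround: float = 1.0,
    slab_y: float = 200.0,
    slab_z: float = 200.0,
    length_x: float = 200.0,
    min_margin: float = 0.0,
    seed: int = 0,
    max_rejections: int = 10_000,
    fill_tol: float = 0.01,
) -> Phantom:
    """Rejection-sample non-overlapping equal-radius cylinders in the slab.

    Centres are drawn uniformly over the admissible region (cylinder fully
    inside the slab); candidates overlapping an accepted cylinder are
    rejected.  Placement stops when the achieved fill reaches
    ``target_fill``, when one more cylinder would overshoot the target by
    more than ``fill_tol`` (relative), or after ``max_rejections``
    consecutive rejections (then a warning is issued and the partial fill
    returned).  The relative tolerance absorbs the discreteness of whole
    cylinder areas: a 200 x 200 um^2 slab at 10 % target takes 12 cylinders
    of r = 10 um (9.42 %) but 51 of r = 5 um (10.01 %).  Deterministic for
    a fixed seed.
    """
    if not 0 <= target_fill < 0.5:
        raise ValueError(f"target_fill must be in [0, 0.5), got {target_fill}")
    if not radius < min(slab_y, slab_z) / 2:
        raise ValueError("radius must be smaller than half the slab extent")

    rng = np.random.default_rng(seed)
    slab_area = slab_y * slab_z
    cyl_area = np.pi * radius**2
    hy, hz = slab_y / 2 - radius, slab_z / 2 - radius

    target_area = target_fill * slab_area
    accepted: list[Cylinder] = []
    rejections = 0
    while (
        len(accepted) * cyl_area < target_area
        and (len(accepted) + 1) * cyl_area <= target_area * (1.0 + fill_tol)
    ):
        cy = rng.uniform(-hy, hy)
        cz = rng.uniform(-hz, hz)
        ok = all(
            np.hypot(cy - c.center_y, cz - c.center_z)
            >= 2 * radius + min_margin
            for c in accepted
        )
        if ok:
            accepted.append(Cylinder(cy, cz, radius, n_cyl))
            rejections = 0
        else:
            rejections += 1
            if rejections >= max_rejections:
                warnings.warn(
                    f"placement stalled after {max_rejections} consecutive "
                    f"rejections: achieved fill "
                    f"{len(accepted) * cyl_area / slab_area:.4f} "
                    f"< target {target_fill:.4f}",
                    stacklevel=2,
                )
                break

    return Phantom(
        cylinders=tuple(accepted),
        slab_y=slab_y,
        slab_z=slab_z,
        length_x=length_x,
        n_surround=n_surround,
        seed=seed,
        achieved_fill=len(accepted) * cyl_area / slab_area,
    )


def tilt_phantom(phantom: Phantom, angle: float) -> Phantom:
    """Rotate all cylinder centres about the slab centre in the y-z plane.

    Emulates a tilted sample (the slab centre is the origin); radii are
    unchanged.  Rotated cylinders may protrude from the nominal slab, so the
    slab cross-section is enlarged to the minimal containing square.
    """
    if not abs(angle) < np.pi / 4:
        raise ValueError("tilt angle must satisfy |angle| < pi/4")
    c, s = np.cos(angle), np.sin(angle)
    new = tuple(
        replace(
            cyl,
            center_y=c * cyl.center_y - s * cyl.center_z,
            center_z=s * cyl.center_y + c * cyl.center_z,
        )
        for cyl in phantom.cylinders
    )
    need = max(
        [2 * (abs(cy.center_y) + cy.radius) for cy in new]
        + [2 * (abs(cy.center_z) + cy.radius) for cy in new],
        default=0.0,
    )
    return replace(
        phantom,
        cylinders=new,
        slab_y=max(phantom.slab_y, need),
        slab_z=max(phantom.slab_z, need),
    )


def write_phantom(phantom: Phantom, path: str | Path) -> None:
    """Serialise a phantom to the versioned JSON schema (lengths in um)."""
    doc = {
        "version": SCHEMA_VERSION,
        "seed": phantom.seed,
        "slab": {"y": phantom.slab_y, "z": phantom.slab_z, "x": phantom.length_x},
        "n_surround": phantom.n_surround,
        "achieved_fill": phantom.achieved_fill,
        "cylinders": [
            {"cy": c.center_y, "cz": c.center_z, "r": c.radius, "n": c.n_cyl}
            for c in phantom.cylinders
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_phantom(path: str | Path) -> Phantom:
    """Read a phantom from JSON, validating schema and geometry."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise PhantomValidationError(f"malformed phantom JSON: {exc}") from exc
    missing = [
        key for key in ("version", "slab", "n_surround", "cylinders") if key not in doc
    ]
    if missing:
        raise PhantomValidationError(f"phantom JSON missing fields: {missing}")
    if doc["version"] != SCHEMA_VERSION:
        raise PhantomValidationError(
            f"unsupported phantom schema version {doc['version']}"
        )
    return Phantom(
        cylinders=tuple(
            Cylinder(c["cy"], c["cz"], c["r"], c["n"]) for c in doc["cylinders"]
        ),
        slab_y=doc["slab"]["y"],
        slab_z=doc["slab"]["z"],
        length_x=doc["slab"]["x"],
        n_surround=doc["n_surround"],
        seed=doc.get("seed"),
        achieved_fill=doc.get("achieved_fill"),
    )


def single_cylinder_phantom(
    radius: float = 10.0,
    n_cyl: float = 1.6285,
    n_surround: float = 1.0,
    slab: float = 200.0,
) -> Phantom:
    """One cylinder centred at the origin — the standard validation scene."""
    return Phantom(
        cylinders=(Cylinder(0.0, 0.0, radius, n_cyl),),
        slab_y=slab,
        slab_z=slab,
        n_surround=n_surround,
    )
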
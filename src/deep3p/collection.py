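"""Collection-side geometry: diffuse emission spread and objective FOV penalty.

Fluorescence generated deep in scattering tissue exits the surface over
a diffuse region whose FWHM is ~1.5x the imaging depth, so collecting
it requires an objective whose collection field of view (FOV) covers
that spread plus the scanned region.  Collection efficiency scales
approximately with NA^2 * FOV^2; an objective whose collection FOV is
smaller than the required one loses light by the squared FOV ratio
(e.g. a 1 mm collection FOV at 2 mm depth with a 0.3 mm scan:
(3.3/1)^2 ~ 11-fold).  Collection FOVs are quoted at 80% throughput,
matching how objectives are specified.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CollectionGeometry",
    "EmissionSpread",
    "emission_spread",
    "required_collection_fov",
    "fov_penalty",
    "collection_gain",
    "combined_improvement",
]

#: FWHM of the diffuse surface emission region per unit imaging depth.
SPREAD_PER_DEPTH = 1.5


@dataclass(frozen=True)
class CollectionGeometry:
    """An objective's collection characteristics.

    ``collection_fov_mm`` is the diameter at 80% throughput;
    ``scan_fov_mm`` is the lateral extent actually scanned.
    """

    collection_na: float
    collection_fov_mm: float
    scan_fov_mm: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.collection_na <= 1.33:
            raise ValueError(
                f"collection NA must be in (0, 1.33], got {self.collection_na}"
            )
        if self.collection_fov_mm <= 0:
            raise ValueError("collection FOV must be > 0")
        if self.scan_fov_mm < 0:
            raise ValueError("scan FOV must be >= 0")


@dataclass(frozen=True)
class EmissionSpread:
    depth_z_mm: float
    fwhm_diameter_mm: float
    required_fov_mm: float


def emission_spread(z_mm: float) -> float:
    """FWHM diameter (mm) of the surface emission region at depth ``z``."""
    if z_mm < 0:
        raise ValueError("depth must be >= 0")
    return SPREAD_PER_DEPTH * z_mm


def required_collection_fov(z_mm: float, scan_fov_mm: float) -> float:
    """Collection FOV needed: emission spread plus the scanned region."""
    if scan_fov_mm < 0:
        raise ValueError("scan FOV must be >= 0")
    return emission_spread(z_mm) + scan_fov_mm


def fov_penalty(geom: CollectionGeometry, z_mm: float, scan_fov_mm: float | None = None) -> float:
    """Fold loss in collection when the required FOV exceeds the objective's.

    ``(required / available)^2`` when the spread does not fit, else 1 —
    no gain is credited for an FOV larger than required.
    """
    scan = geom.scan_fov_mm if scan_fov_mm is None else scan_fov_mm
    required = required_collection_fov(z_mm, scan)
    if required <= geom.collection_fov_mm:
        return 1.0
    return (required / geom.collection_fov_mm) ** 2


def collection_gain(
    a: CollectionGeometry,
    b: CollectionGeometry,
    z_mm: float,
    scan_fov_mm: float,
    include_na: bool = True,
) -> float:
    """Collection-efficiency gain of objective ``a`` over ``b`` at depth z.

    ``(NA_a/NA_b)^2 * penalty(b)/penalty(a)``.  ``include_na=False``
    isolates the FOV factor (whether quoted gains include the NA ratio
    is a matter of convention; both readings are computable).
    """
    gain = fov_penalty(b, z_mm, scan_fov_mm) / fov_penalty(a, z_mm, scan_fov_mm)
    if include_na:
        gain *= (a.collection_na / b.collection_na) ** 2
    return gain


def combined_improvement(excitation_ratio: float, collection_ratio: float) -> float:
    """Total signal improvement: excitation fold times collection fold."""
    if excitation_ratio <= 0 or collection_ratio <= 0:
        raise ValueError("both improvement factors must be > 0")
    return excitation_ratio * collection_ratio
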
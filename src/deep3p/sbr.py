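"""Signal-to-background quantification on deep-tissue image stacks.

The signal-to-background ratio (SBR) of a slice is the mean photon
count inside a signal ROI (e.g. a labelled vessel) divided by the mean
in an adjacent background region; the depth at which the SBR falls to 1
is the imaging depth limit.  This module converts pixel intensities to
absolute photon counts via a measured conversion factor, extracts
line profiles in photons/pulse, builds SBR-vs-depth profiles, locates
the SBR = 1 crossing, and estimates the effective attenuation length
(EAL) from the depth decay of the cube-root signal (three-photon signal
scales as the cube of the focal pulse energy).
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ImageStack",
    "PhotonCalibration",
    "Roi",
    "EalEstimate",
    "pixels_to_photons",
    "fit_conversion_factor",
    "line_profile",
    "sbr",
    "sbr_depth_profile",
    "depth_limit",
    "estimate_eal",
    "histogram_stretch",
]


@dataclass
class ImageStack:
    """A 3-D (z, y, x) stack of integer photon counts with depth metadata.

    ``z_positions_um`` are slice depths ordered surface-first (strictly
    increasing); ``pulses_per_pixel`` is the number of laser pulses
    accumulated per pixel, used for photons-per-pulse conversion.
    """

    voxels: np.ndarray
    pixel_size_um: float
    z_positions_um: np.ndarray
    channel: str = ""
    pulses_per_pixel: int = 1

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.z_positions_um = np.asarray(self.z_positions_um, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D (z, y, x) array")
        if np.any(self.voxels < 0):
            raise ValueError("photon counts must be >= 0")
        if len(self.z_positions_um) != self.voxels.shape[0]:
            raise ValueError("z_positions_um length must match the number of slices")
        if len(self.z_positions_um) > 1 and not np.all(np.diff(self.z_positions_um) > 0):
            raise ValueError("z_positions_um must be strictly increasing")
        if self.pixel_size_um <= 0 or self.pulses_per_pixel <= 0:
            raise ValueError("pixel_size_um and pulses_per_pixel must be > 0")


@dataclass(frozen=True)
class PhotonCalibration:
    """Pixel-intensity -> photon-count conversion under linear conditions."""

    conversion_factor: float
    linear_range_max: float = math.inf

    def __post_init__(self) -> None:
        if self.conversion_factor <= 0:
            raise ValueError("conversion_factor must be > 0")


@dataclass
class Roi:
    """A region of interest on one slice: pixel mask or polyline.

    Coordinates are 0-based (row, col); ``slice_index`` selects the
    z-slice (or frame) the ROI lives on.
    """

    kind: str
    coordinates: np.ndarray  # mask: (n, 2) pixel indices; polyline: (n, 2) vertices
    slice_index: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("mask", "polyline"):
            raise ValueError("Roi kind must be 'mask' or 'polyline'")
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("coordinates must be an (n, 2) array of (row, col)")
        if self.kind == "mask" and len(self.coordinates) == 0:
            raise ValueError("mask ROI must be non-empty")
        if self.kind == "polyline" and len(self.coordinates) < 2:
            raise ValueError("polyline ROI needs at least two vertices")

    @classmethod
    def from_mask(cls, mask: np.ndarray, slice_index: int = 0, label: str = "") -> "Roi":
        rows, cols = np.nonzero(np.asarray(mask))
        return cls(
            kind="mask",
            coordinates=np.column_stack([rows, cols]),
            slice_index=slice_index,
            label=label,
        )

    @classmethod
    def from_polyline(
        cls, vertices, slice_index: int = 0, label: str = ""
    ) -> "Roi":
        return cls(kind="polyline", coordinates=np.asarray(vertices, dtype=float),
                   slice_index=slice_index, label=label)

    def pixel_indices(self) -> tuple[np.ndarray, np.ndarray]:
        if self.kind != "mask":
            raise ValueError("pixel_indices is only defined for mask ROIs")
        idx = self.coordinates.astype(int)
        return idx[:, 0], idx[:, 1]


def pixels_to_photons(values, cal: PhotonCalibration) -> np.ndarray:
    """Convert pixel intensities to photon counts: values x conversion factor.

    Values above the calibration's validated linear range are converted
    anyway but flagged with a warning.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values > cal.linear_range_max):
        _warnings.warn(
            "pixel values exceed the calibrated linear range "
            f"({cal.linear_range_max:g}); converted counts may be biased",
            stacklevel=2,
        )
    return values * cal.conversion_factor


def fit_conversion_factor(pixel_values, photon_counts) -> PhotonCalibration:
    """Fit the photons-per-pixel-value conversion factor (zero intercept).

    Least squares through the origin on paired (pixel value, photon
    count) measurements acquired while varying excitation power.  The
    validated linear range is the largest pixel value whose residual is
    below 10% of the fitted count.
    """
    x = np.asarray(pixel_values, dtype=float)
    y = np.asarray(photon_counts, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pixel_values and photon_counts must be equal-length 1-D")
    if len(x) < 3:
        raise ValueError("at least 3 paired measurements are required")
    if np.any(y <= 0) or np.any(x <= 0):
        raise ValueError("measurements must be positive")
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("degenerate pixel values")
    slope = float(np.dot(x, y)) / sxx
    fitted = slope * x
    ok = np.abs(y - fitted) < 0.10 * fitted
    linear_max = float(x[ok].max()) if np.any(ok) else float(x.min())
    return PhotonCalibration(conversion_factor=slope, linear_range_max=linear_max)


def line_profile(
    stack: ImageStack, roi: Roi, cal: PhotonCalibration | None = None
) -> pd.DataFrame:
    """Photons-per-pulse profile along a polyline ROI on one slice.

    Samples the nearest pixel at 1-pixel arclength steps along each
    segment (no interpolation — counts keep photon semantics), converts
    to photons, and divides by the pulses accumulated per pixel.
    Columns: ``arclength_um``, ``photons_per_pulse``.
    """
    if roi.kind != "polyline":
        raise ValueError("line_profile requires a polyline ROI")
    img = stack.voxels[roi.slice_index].astype(float)
    verts = roi.coordinates
    seglens = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    total = float(seglens.sum())
    if total == 0:
        raise ValueError("polyline has zero length")
    n_samples = int(math.floor(total)) + 1
    s = np.arange(n_samples, dtype=float)  # arclength in pixels
    cum = np.concatenate([[0.0], np.cumsum(seglens)])
    pts = np.empty((n_samples, 2))
    for i, si in enumerate(s):
        j = min(np.searchsorted(cum, si, side="right") - 1, len(seglens) - 1)
        frac = (si - cum[j]) / seglens[j] if seglens[j] > 0 else 0.0
        pts[i] = verts[j] + frac * (verts[j + 1] - verts[j])
    rows = np.clip(np.rint(pts[:, 0]).astype(int), 0, img.shape[0] - 1)
    cols = np.clip(np.rint(pts[:, 1]).astype(int), 0, img.shape[1] - 1)
    values = img[rows, cols]
    factor = cal.conversion_factor if cal is not None else 1.0
    return pd.DataFrame(
        {
            "arclength_um": s * stack.pixel_size_um,
            "photons_per_pulse": values * factor / stack.pulses_per_pixel,
        }
    )


def sbr(
    stack: ImageStack,
    signal_roi: Roi,
    background_roi: Roi,
    slice_index: int | None = None,
) -> float:
    """SBR of one slice: mean signal-ROI count / mean background-ROI count.

    A background mean of exactly zero yields ``inf`` (no pseudo-count is
    added); downstream depth-limit searches skip non-finite rows.
    """
    if slice_index is None:
        if signal_roi.slice_index != background_roi.slice_index:
            raise ValueError("signal and background ROIs must be on the same slice")
        slice_index = signal_roi.slice_index
    img = stack.voxels[slice_index].astype(float)
    sig = float(img[signal_roi.pixel_indices()].mean())
    bg = float(img[background_roi.pixel_indices()].mean())
    if bg == 0:
        return math.inf
    return sig / bg


def sbr_depth_profile(
    stack: ImageStack,
    roi_pairs: dict[int, list[tuple[Roi, Roi]]],
) -> pd.DataFrame:
    """SBR vs depth from per-slice (signal, background) ROI pairs.

    Multiple pairs on a slice are averaged (finite values only) and the
    pair count recorded.  Columns: ``depth_um``, ``sbr``,
    ``signal_mean``, ``background_mean``, ``n_pairs``, ``roi_labels``.
    """
    records = []
    for slice_index in sorted(roi_pairs):
        pairs = roi_pairs[slice_index]
        if not pairs:
            continue
        img = stack.voxels[slice_index].astype(float)
        values, sig_means, bg_means, labels = [], [], [], []
        for sig_roi, bg_roi in pairs:
            s = float(img[sig_roi.pixel_indices()].mean())
            b = float(img[bg_roi.pixel_indices()].mean())
            sig_means.append(s)
            bg_means.append(b)
            values.append(math.inf if b == 0 else s / b)
            labels.append(sig_roi.label or str(slice_index))
        finite = [v for v in values if math.isfinite(v)]
        records.append(
            {
                "depth_um": float(stack.z_positions_um[slice_index]),
                "sbr": float(np.mean(finite)) if finite else math.inf,
                "signal_mean": float(np.mean(sig_means)),
                "background_mean": float(np.mean(bg_means)),
                "n_pairs": len(pairs),
                "roi_labels": ";".join(labels),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["depth_um", "sbr", "signal_mean", "background_mean", "n_pairs", "roi_labels"],
    )


def depth_limit(profile: pd.DataFrame, threshold: float = 1.0) -> float | None:
    """Depth (μm) where the SBR first crosses ``threshold`` from above.

    The crossing between the bracketing slices is located by log-linear
    interpolation (SBR decays ~exponentially with depth).  Returns
    ``None`` when the profile never reaches the threshold.  Slices with
    non-finite SBR (flagged zero-background) are ignored.
    """
    if len(profile) == 0:
        raise ValueError("empty SBR profile")
    rows = profile[np.isfinite(profile["sbr"])].sort_values("depth_um")
    depths = rows["depth_um"].to_numpy()
    values = rows["sbr"].to_numpy()
    for i in range(len(values)):
        if values[i] <= threshold:
            if values[i] == threshold or i == 0:
                return float(depths[i])
            z0, z1 = depths[i - 1], depths[i]
            s0, s1 = values[i - 1], values[i]
            if s0 <= threshold:  # already at/below before; crossing was earlier
                return float(z0)
            frac = math.log(s0 / threshold) / math.log(s0 / s1)
            return float(z0 + frac * (z1 - z0))
    return None


@dataclass(frozen=True)
class EalEstimate:
    eal_um: float
    ci_low_um: float
    ci_high_um: float
    slope_per_um: float
    n_points: int


def estimate_eal(
    depths_um,
    signals,
    surface_energies_nj,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> EalEstimate:
    """EAL from the depth decay of the cube-root, energy-normalised signal.

    Three-photon signal scales as (Esurface·e^{-z/EAL})^3, so
    ln(signal^{1/3} / Esurface) is linear in depth with slope -1/EAL.
    Normalising by the per-slice surface pulse energy handles
    depth-ramped excitation.  The 95% CI is a bootstrap over depth
    points.
    """
    z = np.asarray(depths_um, dtype=float)
    s = np.asarray(signals, dtype=float)
    e = np.asarray(surface_energies_nj, dtype=float)
    if not (z.shape == s.shape == e.shape) or z.ndim != 1:
        raise ValueError("depths, signals and energies must be equal-length 1-D")
    if len(z) < 4:
        raise ValueError("at least 4 depth points are required")
    if np.any(s <= 0) or np.any(e <= 0):
        raise ValueError("signals and surface energies must be > 0")
    y = np.log(np.cbrt(s) / e)

    def _slope(zz, yy):
        return np.polyfit(zz, yy, 1)[0]

    slope = float(_slope(z, y))
    if slope >= 0:
        raise ValueError("no attenuation detected (non-negative depth slope)")
    eal = -1.0 / slope
    rng = np.random.default_rng(seed)
    boots = []
    n = len(z)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        if len(np.unique(z[idx])) < 2:
            continue
        b = _slope(z[idx], y[idx])
        if b < 0:
            boots.append(-1.0 / b)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = eal
    return EalEstimate(
        eal_um=float(eal),
        ci_low_um=float(lo),
        ci_high_um=float(hi),
        slope_per_um=slope,
        n_points=n,
    )


def histogram_stretch(image, saturation_fraction: float = 0.003) -> np.ndarray:
    """Linear display rescale to [0, 1], saturating the brightest pixels.

    The top ``saturation_fraction`` of pixels clip to 1 and the image
    minimum maps to 0 (typical saturation allowance is 0.2-0.5%).  A
    constant image maps to all zeros.
    """
    if not 0.0 <= saturation_fraction <= 0.05:
        raise ValueError("saturation_fraction must lie in [0, 0.05]")
    img = np.asarray(image, dtype=float)
    lo = float(img.min())
    hi = float(np.quantile(img, 1.0 - saturation_fraction))
    if hi <= lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)
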
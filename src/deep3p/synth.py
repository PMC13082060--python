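"""Seeded generators of synthetic image stacks and activity movies.

These emulate the statistical structure the analysis modules assume so
every pipeline is testable without real recordings:

* structural stacks — vascular tubes (and optionally somata) through a
  layered attenuating medium, with a depth-ramped surface pulse energy,
  an SBR that decays log-linearly with depth and crosses 1 at a
  configurable depth limit, and Poisson shot noise on photon counts;
* activity movies — non-overlapping somata with nuclear exclusion
  (annular emission), GCaMP8s-like transients (single-transient
  ΔF/F ~ 0.7, τ1e ~ 0.29 s) on a Poisson photon budget at ~6.18 Hz.

Detector noise beyond shot noise (PMT multiplication noise, dark
counts) is deliberately excluded: deep three-photon detection is
shot-noise limited.  Every generator is deterministic given its seed,
and each returns a ground-truth record sufficient for all downstream
parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detectability import IndicatorKinetics
from .sbr import ImageStack
from .tissue_optics import TissueOpticsModel, attenuation_factor, required_surface_energy
from .traces import ActivityMovie, _frame_averaged_decay

__all__ = [
    "StackRecipe",
    "SessionRecipe",
    "make_structural_stack",
    "spikes_to_rate",
    "make_activity_movie",
    "make_calibration_fixture",
]


@dataclass
class StackRecipe:
    """Recipe for a synthetic structural stack of labelled vasculature.

    ``sbr0`` is the surface SBR and ``depth_limit_um`` the depth where
    the generated SBR reaches 1 (log-linear decay in between).
    ``photon_scale`` is the expected signal photons/pixel at the
    surface.  The surface pulse energy either ramps to hold the focal
    energy constant with depth ("compensating", as done in practice) or
    stays constant.
    """

    shape: tuple[int, int, int] = (28, 64, 64)
    pixel_size_um: float = 1.0
    z_start_um: float = 0.0
    z_step_um: float = 100.0
    n_vessels: int = 4
    vessel_radius_um_range: tuple[float, float] = (2.0, 5.0)
    tissue: TissueOpticsModel = field(default_factory=lambda: TissueOpticsModel.uniform(300.0))
    efocus_target_nj: float = 2.0
    energy_ramp: str = "compensating"
    sbr0: float = 100.0
    depth_limit_um: float = 2500.0
    photon_scale: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sbr0 <= 1:
            raise ValueError("sbr0 must be > 1")
        if self.depth_limit_um <= 0:
            raise ValueError("depth_limit_um must be > 0")
        if self.photon_scale < 0:
            raise ValueError("photon_scale must be >= 0")
        if self.energy_ramp not in ("compensating", "constant"):
            raise ValueError("energy_ramp must be 'compensating' or 'constant'")


def _sbr_at(recipe: StackRecipe, z_um: np.ndarray) -> np.ndarray:
    """Log-linear SBR: sbr0 at z=0 decaying to 1 at the depth limit."""
    return np.exp(np.log(recipe.sbr0) * (1.0 - np.asarray(z_um) / recipe.depth_limit_um))


def make_structural_stack(recipe: StackRecipe) -> tuple[ImageStack, dict]:
    """Render a stack of vessel tubes with depth-decaying SBR.

    Per slice, signal pixels (inside vessels) have expected count
    ``photon_scale x (E(z)·A(z) / (E(0)·A(0)))^3`` and background pixels
    ``signal / SBR(z)``; counts are Poisson.  The ground-truth record
    carries per-slice signal/background masks, the generating SBR
    curve, per-slice surface energies, and the tissue model — enough
    for SBR, depth-limit and EAL recovery without touching generator
    internals.
    """
    nz, ny, nx = recipe.shape
    if recipe.n_vessels < 1:
        raise ValueError("at least one vessel is required (empty geometry)")
    rng = np.random.default_rng(recipe.seed)
    z = recipe.z_start_um + recipe.z_step_um * np.arange(nz)

    atten = attenuation_factor(recipe.tissue, z)
    if recipe.energy_ramp == "compensating":
        energies = required_surface_energy(recipe.efocus_target_nj, recipe.tissue, z)
    else:
        energies = np.full(nz, recipe.efocus_target_nj / atten[0])
    efocus = energies * atten
    signal = recipe.photon_scale * (efocus / efocus[0]) ** 3
    sbr_true = _sbr_at(recipe, z)
    background = signal / sbr_true

    # sinusoidal vessel tubes running along y, wobbling in x across depth
    lo_r, hi_r = recipe.vessel_radius_um_range
    radii_px = rng.uniform(lo_r, hi_r, recipe.n_vessels) / recipe.pixel_size_um
    x0 = rng.uniform(hi_r + 2, nx - hi_r - 2, recipe.n_vessels)
    amp = rng.uniform(0, 3.0, recipe.n_vessels)
    phase = rng.uniform(0, 2 * math.pi, recipe.n_vessels)
    cols = np.arange(nx)

    fg_masks = np.zeros((nz, ny, nx), dtype=bool)
    bg_masks = np.zeros((nz, ny, nx), dtype=bool)
    voxels = np.zeros((nz, ny, nx), dtype=np.uint32)
    margin = 3.0  # px between vessel wall and "adjacent background"
    for k in range(nz):
        near = np.zeros(nx, dtype=bool)
        fg_cols = np.zeros(nx, dtype=bool)
        for v in range(recipe.n_vessels):
            xc = x0[v] + amp[v] * math.sin(2 * math.pi * k / max(nz, 1) + phase[v])
            dist = np.abs(cols - xc)
            fg_cols |= dist <= radii_px[v]
            near |= dist <= radii_px[v] + margin
        fg_masks[k, :, fg_cols] = True
        bg_masks[k, :, ~near] = True
        lam = np.where(fg_masks[k], signal[k], background[k])
        voxels[k] = rng.poisson(lam)

    stack = ImageStack(
        voxels=voxels,
        pixel_size_um=recipe.pixel_size_um,
        z_positions_um=z,
        channel="synthetic-vessels",
    )
    ground_truth = {
        "signal_masks": fg_masks,
        "background_masks": bg_masks,
        "sbr": sbr_true,
        "depth_limit_um": recipe.depth_limit_um,
        "signal_photons": signal,
        "background_photons": background,
        "surface_energies_nj": np.asarray(energies),
        "tissue": recipe.tissue,
        "z_positions_um": z,
        "seed": recipe.seed,
    }
    return stack, ground_truth


def spikes_to_rate(
    spike_times_s,
    kin: IndicatorKinetics,
    f0_photons_per_s: float,
    duration_s: float,
    dt_s: float,
) -> np.ndarray:
    """Instantaneous photon rate from a spike train (linear superposition).

    ``rate(t) = F0 · (1 + Σ_s ΔF/F · e^{-(t - t_s)/τ1e} · 1[t >= t_s])``
    sampled at t = k·dt.
    """
    spikes = np.asarray(spike_times_s, dtype=float)
    if np.any((spikes < 0) | (spikes >= duration_s)):
        raise ValueError("spike times must lie within [0, duration)")
    t = np.arange(int(round(duration_s / dt_s))) * dt_s
    modulation = np.zeros_like(t)
    for ts in spikes:
        active = t >= ts
        modulation[active] += np.exp(-(t[active] - ts) / kin.tau_1e_s)
    return f0_photons_per_s * (1.0 + kin.dff_single_transient * modulation)


@dataclass
class SessionRecipe:
    """Recipe for a synthetic functional-imaging session.

    Defaults follow the deep-imaging acquisition configuration this
    toolkit targets: 100 μm field of view at 120 x 120 pixels, 6.18 Hz
    frame rate, up to 44 simultaneously recorded neurons of 10-15 μm
    soma diameter with nuclear exclusion, sparse spontaneous activity,
    and a baseline budget of 300 photons/neuron/s (comfortably above
    the 150 photons/neuron/s fidelity threshold, at the ~99%
    single-transient detection point).  Background is a small uniform
    photon rate per pixel, consistent with the strong background
    suppression of three-photon excitation.
    """

    n_neurons: int = 44
    fov_um: float = 100.0
    frame_shape: tuple[int, int] = (120, 120)
    frame_rate_hz: float = 6.18
    duration_s: float = 120.0
    kinetics: IndicatorKinetics = field(default_factory=IndicatorKinetics)
    spike_rate_hz: float = 0.1
    baseline_rate_f0: float = 300.0
    background_rate_per_pixel_s: float = 0.1
    soma_diameter_um_range: tuple[float, float] = (10.0, 15.0)
    ring_width_px: int = 2
    ring_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be >= 0")
        for name in ("fov_um", "frame_rate_hz", "duration_s", "baseline_rate_f0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.spike_rate_hz < 0 or self.background_rate_per_pixel_s < 0:
            raise ValueError("rates must be >= 0")
        if not 0 < self.ring_fraction <= 1:
            raise ValueError("ring_fraction must lie in (0, 1]")

    @property
    def pixel_size_um(self) -> float:
        return self.fov_um / self.frame_shape[1]


def _place_somata(recipe: SessionRecipe, rng: np.random.Generator):
    """Non-overlapping soma centres and radii via a jittered lattice.

    At 44 neurons in 120 x 120 px, 10-15 μm somata approach the jamming
    density of random sequential placement, so somata are assigned to
    shuffled lattice cells with sub-cell jitter; radii are drawn from
    the diameter range and clipped to the cell half-pitch, which
    guarantees disjoint masks by construction.
    """
    ny, nx = recipe.frame_shape
    n = recipe.n_neurons
    ncols = max(1, math.ceil(math.sqrt(n * nx / ny)))
    nrows = max(1, math.ceil(n / ncols))
    while ncols * nrows < n:
        nrows += 1
    cell_h, cell_w = ny / nrows, nx / ncols
    jitter = 1.0
    r_cap_px = min(cell_h, cell_w) / 2.0 - jitter - 0.5
    if r_cap_px < 1.0:
        raise ValueError(
            f"cannot place {n} non-overlapping somata in a {ny}x{nx} frame"
        )
    cells = [(r, c) for r in range(nrows) for c in range(ncols)]
    rng.shuffle(cells)
    lo_d, hi_d = recipe.soma_diameter_um_range
    hi_d = min(hi_d, 2 * r_cap_px * recipe.pixel_size_um)
    if hi_d < lo_d:
        lo_d = hi_d
    centers, radii = [], []
    for r, c in cells[:n]:
        cy = (r + 0.5) * cell_h + rng.uniform(-jitter, jitter)
        cx = (c + 0.5) * cell_w + rng.uniform(-jitter, jitter)
        diam_um = rng.uniform(lo_d, hi_d)
        radii.append(min(diam_um / 2.0 / recipe.pixel_size_um, r_cap_px))
        centers.append((cy, cx))
    return centers, radii


def make_activity_movie(recipe: SessionRecipe) -> tuple[ActivityMovie, dict]:
    """Simulate a functional session: somata, spikes, Poisson photons.

    Each neuron's baseline budget ``baseline_rate_f0`` is split over its
    soma pixels with ``ring_fraction`` of the photons in a cytoplasmic
    ring of ``ring_width_px`` (nuclear exclusion) and the remainder in
    the interior; spike trains are homogeneous Poisson processes and
    transient modulation is integrated exactly over each frame.  The
    ground truth returns spike times, per-neuron masks, per-frame rates
    and the expected ROI baseline (neuron + background photons).
    """
    ny, nx = recipe.frame_shape
    rng = np.random.default_rng(recipe.seed)
    dt = 1.0 / recipe.frame_rate_hz
    n_frames = int(round(recipe.duration_s * recipe.frame_rate_hz))
    if n_frames < 1:
        raise ValueError("duration too short for a single frame")
    kin = recipe.kinetics

    centers, radii = _place_somata(recipe, rng) if recipe.n_neurons else ([], [])
    yy, xx = np.mgrid[0:ny, 0:nx]

    rate_movie = np.full(
        (n_frames, ny, nx),
        recipe.background_rate_per_pixel_s * dt,
        dtype=np.float64,
    )
    masks, weights_list, spike_trains, frame_rates = [], [], [], []
    for (cy, cx), r in zip(centers, radii):
        dist = np.hypot(yy - cy, xx - cx)
        disk = dist <= r
        ring = disk & (dist >= r - recipe.ring_width_px)
        inner = disk & ~ring
        w = np.zeros((ny, nx))
        if inner.sum() == 0:
            w[ring] = 1.0 / ring.sum()
        else:
            w[ring] = recipe.ring_fraction / ring.sum()
            w[inner] = (1.0 - recipe.ring_fraction) / inner.sum()
        # homogeneous Poisson spike train over the session
        n_spikes = rng.poisson(recipe.spike_rate_hz * recipe.duration_s)
        spikes = np.sort(rng.uniform(0, recipe.duration_s, n_spikes))
        # exact per-frame integral of the transient modulation
        modulation = np.zeros(n_frames)
        for ts in spikes:
            i0 = int(ts / dt)
            rel = np.arange(n_frames - i0, dtype=float)
            modulation[i0:] += _frame_averaged_decay(rel, ts - i0 * dt, kin.tau_1e_s, dt)
        neuron_rate = recipe.baseline_rate_f0 * (
            1.0 + kin.dff_single_transient * modulation
        )  # photons/s, frame-averaged
        ys, xs = np.nonzero(disk)
        rate_movie[:, ys, xs] += np.outer(neuron_rate * dt, w[ys, xs])
        masks.append(disk)
        weights_list.append(w)
        spike_trains.append(spikes)
        frame_rates.append(neuron_rate)

    frames = rng.poisson(rate_movie).astype(np.uint16)
    movie = ActivityMovie(
        frames=frames,
        frame_rate_hz=recipe.frame_rate_hz,
        pixel_size_um=recipe.pixel_size_um,
    )
    roi_baseline = [
        recipe.baseline_rate_f0
        + recipe.background_rate_per_pixel_s * int(m.sum())
        for m in masks
    ]
    ground_truth = {
        "masks": masks,
        "weights": weights_list,
        "spike_times_s": spike_trains,
        "frame_rates_photons_s": frame_rates,
        "roi_baseline_photons_s": np.asarray(roi_baseline),
        "baseline_rate_f0": recipe.baseline_rate_f0,
        "background_rate_per_pixel_s": recipe.background_rate_per_pixel_s,
        "kinetics": kin,
        "frame_rate_hz": recipe.frame_rate_hz,
        "seed": recipe.seed,
    }
    return movie, ground_truth


def make_calibration_fixture(
    true_factor: float,
    n_points: int = 20,
    noise: str | None = "poisson",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (pixel value, photon count) measurements on a known line.

    ``noise="poisson"`` draws the counts from Poisson(factor x pixels);
    ``noise=None`` returns the exact line.
    """
    if true_factor <= 0:
        raise ValueError("true_factor must be > 0")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    pixel_values = np.linspace(20.0, 400.0, n_points)
    expected = true_factor * pixel_values
    if noise is None:
        return pixel_values, expected
    if noise != "poisson":
        raise ValueError("noise must be 'poisson' or None")
    rng = np.random.default_rng(seed)
    return pixel_values, rng.poisson(expected).astype(float)
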
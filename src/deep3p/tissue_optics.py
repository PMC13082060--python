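"""Excitation-side photon budget for deep three-photon microscopy.

Three-photon (3P) fluorescence generated by a pulsed laser scales as

    <F(t)> ∝ Pfocus^3 / (f τ)^2  =  Efocus^2 · Pfocus / τ^2

where ``f`` is the repetition rate, ``τ`` the pulse width, ``Pfocus`` the
average power at the focus and ``Efocus = Pfocus / f`` the focal pulse
energy.  Ballistic excitation light attenuates exponentially with depth
``z`` through scattering tissue, ``Pfocus = Psurface · exp(-z/EAL)``,
where the EAL (effective attenuation length) combines scattering and
absorption.  Holding the surface power at the heating limit and the
focal pulse energy at the damage/saturation limit, the repetition rate
that realises both is ``f(z) = exp(-z/EAL) · Psurface / Efocus``, i.e.
50 MHz at the surface for 100 mW / 2 nJ, falling to ~100 kHz at depths
of several EALs.

Only signal *ratios* are physically meaningful here: fluorophore cross
sections, collection efficiency and quantum yield are not modelled, so
all proportionality constants are fixed to 1.

Units: depths and EALs in μm, energies in nJ, average powers in mW,
rates in Hz, times in s.  Every numeric field carries its unit in its
name; conversions happen only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "LaserConfig",
    "TissueOpticsModel",
    "SignalEstimate",
    "ConstraintViolation",
    "attenuation_factor",
    "focus_pulse_energy",
    "required_surface_energy",
    "optimal_rep_rate",
    "relative_signal",
    "signal_ratio",
    "check_constraints",
    "calibrate_depth",
]

# 1 nJ * 1 Hz = 1e-9 W = 1e-6 mW
_NJ_HZ_TO_MW = 1e-6


@dataclass(frozen=True)
class LaserConfig:
    """Excitation source state.

    The surface average power, repetition rate and surface pulse energy
    are redundant (``Psurface = f · Esurface``); consistency is enforced
    on construction to 1e-9 relative tolerance.  Use
    :meth:`from_rep_rate` or :meth:`from_power` to supply only two of
    the three.
    """

    repetition_rate_hz: float
    pulse_width_s: float
    surface_power_mw: float
    surface_pulse_energy_nj: float
    focus_pulse_energy_nj: float | None = None
    wavelength_nm: float = 1300.0

    def __post_init__(self) -> None:
        for name in (
            "repetition_rate_hz",
            "pulse_width_s",
            "surface_power_mw",
            "surface_pulse_energy_nj",
            "wavelength_nm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        implied_mw = self.repetition_rate_hz * self.surface_pulse_energy_nj * _NJ_HZ_TO_MW
        if not math.isclose(implied_mw, self.surface_power_mw, rel_tol=1e-9):
            raise ValueError(
                "inconsistent laser config: f*Esurface = "
                f"{implied_mw:g} mW but surface_power_mw = {self.surface_power_mw:g}"
            )
        if self.focus_pulse_energy_nj is not None:
            if self.focus_pulse_energy_nj <= 0:
                raise ValueError("focus_pulse_energy_nj must be > 0 when given")
            if self.focus_pulse_energy_nj > self.surface_pulse_energy_nj * (1 + 1e-12):
                raise ValueError(
                    "focus pulse energy cannot exceed surface pulse energy"
                )

    @classmethod
    def from_rep_rate(
        cls,
        repetition_rate_hz: float,
        surface_pulse_energy_nj: float,
        pulse_width_s: float = 60e-15,
        **kw,
    ) -> "LaserConfig":
        return cls(
            repetition_rate_hz=repetition_rate_hz,
            pulse_width_s=pulse_width_s,
            surface_power_mw=repetition_rate_hz * surface_pulse_energy_nj * _NJ_HZ_TO_MW,
            surface_pulse_energy_nj=surface_pulse_energy_nj,
            **kw,
        )

    @classmethod
    def from_power(
        cls,
        surface_power_mw: float,
        repetition_rate_hz: float,
        pulse_width_s: float = 60e-15,
        **kw,
    ) -> "LaserConfig":
        return cls(
            repetition_rate_hz=repetition_rate_hz,
            pulse_width_s=pulse_width_s,
            surface_power_mw=surface_power_mw,
            surface_pulse_energy_nj=surface_power_mw / (repetition_rate_hz * _NJ_HZ_TO_MW),
            **kw,
        )


@dataclass(frozen=True)
class TissueOpticsModel:
    """Piecewise-constant EAL layers, ordered surface-down.

    ``layers`` is a sequence of ``(thickness_um, eal_um)`` pairs; the
    deepest layer is extended to infinity when a queried depth exceeds
    the total stated thickness.  ``depth_calibration_factor`` corrects
    raw objective-displacement depths for the tissue/water refractive
    index mismatch (tissue depths are underestimated by ~5-10%; default
    is the midpoint 1.075).
    """

    layers: tuple[tuple[float, float], ...]
    depth_calibration_factor: float = 1.075

    def __post_init__(self) -> None:
        layers = tuple((float(t), float(e)) for t, e in self.layers)
        object.__setattr__(self, "layers", layers)
        if not layers:
            raise ValueError("at least one tissue layer is required")
        for t, e in layers:
            if t <= 0 or e <= 0:
                raise ValueError(f"layer thickness and EAL must be > 0, got ({t}, {e})")
        if not 1.0 <= self.depth_calibration_factor <= 1.2:
            raise ValueError(
                "depth_calibration_factor must lie in [1.0, 1.2], got "
                f"{self.depth_calibration_factor}"
            )

    @classmethod
    def uniform(cls, eal_um: float, thickness_um: float = 1e7, **kw) -> "TissueOpticsModel":
        """A single homogeneous layer (effectively semi-infinite)."""
        return cls(layers=((thickness_um, eal_um),), **kw)


@dataclass(frozen=True)
class SignalEstimate:
    """Relative time-averaged 3P signal at a depth (proportional units)."""

    relative_signal: float
    depth_z_um: float

    def __post_init__(self) -> None:
        if self.relative_signal < 0:
            raise ValueError("relative_signal must be >= 0")


@dataclass(frozen=True)
class ConstraintViolation:
    quantity: str
    value: float
    limit: float


def attenuation_factor(tissue: TissueOpticsModel, z_um) -> float | np.ndarray:
    """Ballistic power attenuation exp(-Σ Δz_i / EAL_i) down to depth ``z``.

    Accepts a scalar or array depth; the deepest layer extends
    indefinitely beyond the stated total thickness.  Equals
    ``exp(-z/EAL)`` for a uniform medium.
    """
    z = np.asarray(z_um, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth z must be >= 0")
    optical = np.zeros_like(z)
    top = 0.0
    remaining = z.copy()
    for i, (thickness, eal) in enumerate(tissue.layers):
        if i == len(tissue.layers) - 1:
            seg = np.clip(remaining, 0.0, None)  # last layer: no lower bound
        else:
            seg = np.clip(remaining, 0.0, thickness)
        optical += seg / eal
        remaining -= seg
        top += thickness
    out = np.exp(-optical)
    return float(out) if np.isscalar(z_um) or out.ndim == 0 else out


def focus_pulse_energy(
    surface_pulse_energy_nj: float, tissue: TissueOpticsModel, z_um
) -> float | np.ndarray:
    """Pulse energy reaching the focus: Esurface · exp(-z/EAL)."""
    if np.any(np.asarray(surface_pulse_energy_nj) <= 0):
        raise ValueError("surface pulse energy must be > 0")
    return surface_pulse_energy_nj * attenuation_factor(tissue, z_um)


def required_surface_energy(
    focus_pulse_energy_target_nj: float, tissue: TissueOpticsModel, z_um
) -> float | np.ndarray:
    """Surface pulse energy needed for a target focal energy at depth z.

    Exact inverse of :func:`focus_pulse_energy`:
    ``Esurface = e^{z/EAL} · Efocus``.
    """
    if np.any(np.asarray(focus_pulse_energy_target_nj) <= 0):
        raise ValueError("target focus pulse energy must be > 0")
    return focus_pulse_energy_target_nj / attenuation_factor(tissue, z_um)


def optimal_rep_rate(
    tissue: TissueOpticsModel,
    z_um,
    psurface_max_mw: float = 100.0,
    efocus_max_nj: float = 2.0,
) -> float | np.ndarray:
    """Repetition rate saturating both power budgets at depth z (Hz).

    ``f(z) = e^{-z/EAL} · Psurface_max / Efocus_max``; with the default
    100 mW / 2 nJ limits this is 50 MHz at the surface.
    """
    if psurface_max_mw <= 0 or efocus_max_nj <= 0:
        raise ValueError("power and energy limits must be > 0")
    f_surface_hz = psurface_max_mw / (efocus_max_nj * _NJ_HZ_TO_MW)
    return attenuation_factor(tissue, z_um) * f_surface_hz


def relative_signal(
    config: LaserConfig, tissue: TissueOpticsModel, z_um: float
) -> SignalEstimate:
    """Time-averaged 3P signal Efocus(z)^2 · Pfocus(z) / τ^2, constant = 1."""
    a = attenuation_factor(tissue, z_um)
    efocus = config.surface_pulse_energy_nj * a
    pfocus = config.surface_power_mw * a
    value = efocus**2 * pfocus / config.pulse_width_s**2
    return SignalEstimate(relative_signal=float(value), depth_z_um=float(z_um))


def signal_ratio(
    a: LaserConfig,
    b: LaserConfig,
    tissue: TissueOpticsModel,
    z_um: float,
    allow_unequal_tau: bool = False,
) -> float:
    """Fold-change in 3P signal of config ``a`` over config ``b``.

    Comparisons assume equal pulse width unless ``allow_unequal_tau``;
    the (fτ)^2 denominator then enters the ratio.
    """
    if not allow_unequal_tau and not math.isclose(
        a.pulse_width_s, b.pulse_width_s, rel_tol=1e-9
    ):
        raise ValueError(
            "configs have different pulse widths; pass allow_unequal_tau=True "
            "to compare via the (f*tau)^2 term"
        )
    denom = relative_signal(b, tissue, z_um).relative_signal
    if denom == 0:
        raise ValueError("signal of config b is zero; ratio undefined")
    return relative_signal(a, tissue, z_um).relative_signal / denom


def check_constraints(
    config: LaserConfig,
    psurface_limit_mw: float = 100.0,
    efocus_limit_nj: float = 2.0,
) -> list[ConstraintViolation]:
    """Check the heating (surface power) and damage (focal energy) limits.

    Violations are returned as data, not raised; an empty list means the
    configuration respects both limits.  The focal energy checked is the
    config's ``focus_pulse_energy_nj`` if set, else the surface energy
    (the z=0 worst case).
    """
    violations: list[ConstraintViolation] = []
    if config.surface_power_mw > psurface_limit_mw * (1 + 1e-12):
        violations.append(
            ConstraintViolation(
                "surface_power_mw", config.surface_power_mw, psurface_limit_mw
            )
        )
    efocus = (
        config.focus_pulse_energy_nj
        if config.focus_pulse_energy_nj is not None
        else config.surface_pulse_energy_nj
    )
    if efocus > efocus_limit_nj * (1 + 1e-12):
        violations.append(
            ConstraintViolation("focus_pulse_energy_nj", efocus, efocus_limit_nj)
        )
    return violations


def calibrate_depth(raw_depth_um, tissue: TissueOpticsModel) -> float | np.ndarray:
    """Correct a raw (objective-displacement) depth for refractive mismatch."""
    z = np.asarray(raw_depth_um, dtype=float)
    if np.any(z < 0):
        raise ValueError("raw depth must be >= 0")
    out = z * tissue.depth_calibration_factor
    return float(out) if out.ndim == 0 else out
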
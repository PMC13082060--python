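"""Schema-checked run configuration (YAML/JSON) for the command line.

Sections: ``laser``, ``tissue``, ``collection`` (named geometries),
``kinetics``, ``pipeline``.  Unknown keys are rejected by name so a
typo fails loudly instead of silently falling back to a default.  All
keys carry their unit as a suffix.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .collection import CollectionGeometry
from .detectability import IndicatorKinetics
from .tissue_optics import LaserConfig, TissueOpticsModel

__all__ = ["ConfigError", "RunConfig", "load_config", "DEFAULT_CONFIG"]


class ConfigError(ValueError):
    """A configuration file violated the schema."""


_SCHEMA = {
    "laser": {"f_hz", "tau_s", "psurface_mw", "esurface_nj", "wavelength_nm"},
    "tissue": {"layers", "depth_factor"},
    "collection": None,  # mapping of name -> geometry dict
    "kinetics": {"dff", "tau_1e_s", "t12_s"},
    "pipeline": {
        "lowpass_tc_s",
        "baseline_fraction",
        "min_rate_photons_s",
        "discard_initial_s",
        "median_rx",
        "median_ry",
        "median_rt",
        "trim_frames",
    },
}
_GEOMETRY_KEYS = {"na", "collection_fov_mm", "scan_fov_mm"}
_LAYER_KEYS = {"thickness_um", "eal_um"}

DEFAULT_CONFIG: dict = {
    "laser": {"f_hz": 1e5, "tau_s": 60e-15, "esurface_nj": 1000.0},
    "tissue": {"layers": [{"thickness_um": 1e7, "eal_um": 300.0}], "depth_factor": 1.075},
    "collection": {
        "conventional": {"na": 1.05, "collection_fov_mm": 1.0, "scan_fov_mm": 0.3},
        "lfov": {"na": 1.0, "collection_fov_mm": 4.0, "scan_fov_mm": 0.3},
    },
    "kinetics": {"dff": 0.7, "tau_1e_s": 0.29},
    "pipeline": {
        "lowpass_tc_s": 0.29,
        "baseline_fraction": 0.20,
        "min_rate_photons_s": 150.0,
        "discard_initial_s": 0.0,
        "median_rx": 1,
        "median_ry": 1,
        "median_rt": 18,
        "trim_frames": 9,
    },
}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


class RunConfig:
    """Validated configuration with domain objects built on demand."""

    def __init__(self, raw: dict):
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        _check_keys(raw, set(_SCHEMA), "config root")
        merged = {k: dict(DEFAULT_CONFIG[k]) for k in DEFAULT_CONFIG}
        for section, content in raw.items():
            if not isinstance(content, dict):
                raise ConfigError(f"section '{section}' must be a mapping")
            if _SCHEMA[section] is not None:
                _check_keys(content, _SCHEMA[section], f"section '{section}'")
            else:
                for name, geom in content.items():
                    if not isinstance(geom, dict):
                        raise ConfigError(f"collection '{name}' must be a mapping")
                    _check_keys(geom, _GEOMETRY_KEYS, f"collection '{name}'")
            merged[section].update(content)
        for layer in merged["tissue"]["layers"]:
            if not isinstance(layer, dict):
                raise ConfigError("tissue layers must be mappings")
            _check_keys(layer, _LAYER_KEYS, "tissue layer")
        self.raw = merged

    def laser(self) -> LaserConfig:
        sec = self.raw["laser"]
        return LaserConfig.from_rep_rate(
            repetition_rate_hz=sec["f_hz"],
            surface_pulse_energy_nj=sec["esurface_nj"],
            pulse_width_s=sec["tau_s"],
            wavelength_nm=sec.get("wavelength_nm", 1300.0),
        )

    def tissue(self) -> TissueOpticsModel:
        sec = self.raw["tissue"]
        return TissueOpticsModel(
            layers=tuple((l["thickness_um"], l["eal_um"]) for l in sec["layers"]),
            depth_calibration_factor=sec.get("depth_factor", 1.075),
        )

    def geometry(self, name: str) -> CollectionGeometry:
        try:
            geom = self.raw["collection"][name]
        except KeyError:
            raise ConfigError(f"no collection geometry named '{name}'") from None
        return CollectionGeometry(
            collection_na=geom["na"],
            collection_fov_mm=geom["collection_fov_mm"],
            scan_fov_mm=geom.get("scan_fov_mm", 0.0),
            name=name,
        )

    def kinetics(self) -> IndicatorKinetics:
        sec = self.raw["kinetics"]
        if "t12_s" in sec and "tau_1e_s" not in sec:
            return IndicatorKinetics.from_half_life(sec["t12_s"], sec.get("dff", 0.7))
        return IndicatorKinetics(
            dff_single_transient=sec.get("dff", 0.7),
            tau_1e_s=sec.get("tau_1e_s", 0.29),
            half_life_t12_s=sec.get("t12_s"),
        )

    def pipeline(self) -> dict:
        return dict(self.raw["pipeline"])

    def digest(self) -> str:
        import hashlib

        blob = json.dumps(self.raw, sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config file; ``None`` yields the defaults."""
    if path is None:
        return RunConfig({})
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    return RunConfig(raw)
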
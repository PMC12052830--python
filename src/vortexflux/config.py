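"""Run configuration: TOML parsing, defaults and validation.

A run is described by a small flat config file with sections::

    [beam]            # l, p, w_nm, n
    [pattern]         # kind = "four_point" | "raster", L_nm, raster_dim
    [noise]           # sbr (omit or inf = noiseless), anchor_L_nm, sbr_mode
    [photons]         # N
    [map]             # roi_half_width_nm, step_nm
    [efov]            # threshold_nm, definition
    [optimal_L]       # lo_nm, hi_nm
    [prior]           # std_nm
    [simulation]      # trials, seed, rows, cols, spacing_nm

All lengths are in nm.  Every field has a default, so an empty file is a
valid run (first-order vortex, w = 300 nm, four-point L = 50 nm, N = 100,
SBR = 4 anchored at the pattern size, all_exposures convention).  The
fully resolved configuration is embedded in every output for
reproducibility.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .beams import VortexBeam
from .patterns import ExposurePattern, make_four_point_tcp, make_raster_tcp
from .photon_model import PhotonModel

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]

_DEFAULTS = {
    "beam": {"l": 1, "p": 0, "w_nm": 300.0, "n": 1},
    "pattern": {"kind": "four_point", "L_nm": 50.0, "raster_dim": 4},
    "noise": {"sbr": 4.0, "anchor_L_nm": None, "sbr_mode": "all_exposures"},
    "photons": {"N": 100},
    "map": {"roi_half_width_nm": 30.0, "step_nm": 1.0},
    "efov": {"threshold_nm": 4.0, "definition": "worst_case"},
    "optimal_L": {"lo_nm": 10.0, "hi_nm": 100.0},
    "prior": {"std_nm": 50.0},
    "simulation": {"trials": 500, "seed": 1, "rows": 3, "cols": 3,
                   "spacing_nm": 5.0},
}


class ConfigError(ValueError):
    """Invalid run configuration; message carries the field path."""


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run configuration."""

    model: PhotonModel
    map_roi_half_width: float
    map_step: float
    efov_threshold: float
    efov_definition: str
    optimal_L_range: tuple[float, float]
    prior_std: float
    trials: int
    seed: int
    array_shape: tuple[int, int]
    array_spacing: float
    resolved: dict = field(repr=False, default_factory=dict)


def _merge(raw: dict) -> dict:
    cfg = {}
    for section, defaults in _DEFAULTS.items():
        got = raw.get(section, {})
        if not isinstance(got, dict):
            raise ConfigError(f"{section}: expected a table/section")
        unknown = set(got) - set(defaults)
        if unknown:
            raise ConfigError(
                f"{section}: unknown key(s) {sorted(unknown)}"
            )
        cfg[section] = {**defaults, **got}
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown section(s) {sorted(unknown)}")
    return cfg


def validate_config(raw: dict, task: str | None = None) -> RunConfig:
    """Apply defaults and validate a raw (parsed) configuration mapping.

    ``task`` enables task-specific checks, e.g. the four-point closed form
    and doughnut-requiring analyses reject ``l = 0`` and pattern sizes
    beyond the validity of the central bound.
    """
    cfg = _merge(raw)
    b = cfg["beam"]
    try:
        beam = VortexBeam(l=int(b["l"]), p=int(b["p"]),
                          waist=float(b["w_nm"]), photon_order=int(b["n"]))
    except ValueError as e:
        raise ConfigError(f"beam: {e}") from None

    p = cfg["pattern"]
    try:
        if p["kind"] == "four_point":
            pattern = make_four_point_tcp(float(p["L_nm"]))
        elif p["kind"] == "raster":
            pattern = make_raster_tcp(float(p["L_nm"]), int(p["raster_dim"]))
        else:
            raise ConfigError(
                f"pattern.kind: expected four_point or raster, got {p['kind']!r}"
            )
    except ValueError as e:
        raise ConfigError(f"pattern: {e}") from None

    nz = cfg["noise"]
    sbr = nz["sbr"]
    sbr = math.inf if sbr in (None, "inf") else float(sbr)
    anchor = nz["anchor_L_nm"]
    try:
        model = PhotonModel(
            beam=beam,
            pattern=pattern,
            n_photons=int(cfg["photons"]["N"]),
            sbr=sbr,
            sbr_anchor_L=None if anchor is None else float(anchor),
            sbr_mode=str(nz["sbr_mode"]),
        )
    except ValueError as e:
        raise ConfigError(f"noise/photons: {e}") from None

    if task in ("crb-center", "crb-map", "opt-L", "efov", "bayes", "simulate"):
        if beam.abs_l < 1:
            raise ConfigError(
                "beam.l: a vortex (|l| >= 1) is required for localization "
                "analyses; l = 0 has no central dark spot"
            )
        L = pattern.size
        if L**2 >= 2 * beam.abs_l * beam.waist**2:
            raise ConfigError(
                f"pattern.L_nm: L = {L} exceeds the validity range "
                f"L^2 < 2|l|w^2 = {2 * beam.abs_l * beam.waist**2:.0f} nm^2"
            )

    mp, ef, oL, pr, sim = (cfg["map"], cfg["efov"], cfg["optimal_L"],
                           cfg["prior"], cfg["simulation"])
    if mp["step_nm"] <= 0 or mp["roi_half_width_nm"] <= 0:
        raise ConfigError("map: roi_half_width_nm and step_nm must be > 0")
    if ef["threshold_nm"] <= 0:
        raise ConfigError("efov.threshold_nm: must be > 0")
    if ef["definition"] not in ("worst_case", "azimuthal_mean"):
        raise ConfigError(f"efov.definition: unknown {ef['definition']!r}")
    if not (0 < oL["lo_nm"] < oL["hi_nm"]):
        raise ConfigError("optimal_L: need 0 < lo_nm < hi_nm")
    if pr["std_nm"] <= 0:
        raise ConfigError("prior.std_nm: must be > 0")
    if sim["trials"] < 1 or sim["rows"] < 1 or sim["cols"] < 1 \
            or sim["spacing_nm"] <= 0:
        raise ConfigError("simulation: trials/rows/cols >= 1, spacing_nm > 0")

    resolved = {**cfg}
    resolved["noise"]["sbr"] = sbr if math.isfinite(sbr) else "inf"
    resolved["noise"]["anchor_L_nm"] = model.sbr_anchor_L
    return RunConfig(
        model=model,
        map_roi_half_width=float(mp["roi_half_width_nm"]),
        map_step=float(mp["step_nm"]),
        efov_threshold=float(ef["threshold_nm"]),
        efov_definition=str(ef["definition"]),
        optimal_L_range=(float(oL["lo_nm"]), float(oL["hi_nm"])),
        prior_std=float(pr["std_nm"]),
        trials=int(sim["trials"]),
        seed=int(sim["seed"]),
        array_shape=(int(sim["rows"]), int(sim["cols"])),
        array_spacing=float(sim["spacing_nm"]),
        resolved=resolved,
    )


def load_config(path, task: str | None = None) -> RunConfig:
    """Parse a TOML run-config file and validate it."""
    text = Path(path).read_bytes()
    try:
        raw = tomllib.loads(text.decode())
    except tomllib.TOMLDecodeError as e:
        raise ConfigError(f"config parse error: {e}") from None
    return validate_config(raw, task=task)
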
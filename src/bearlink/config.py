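"""Pipeline configuration with field-anchored defaults.

Every threshold default is the one used in the field protocol: PDOP < 10,
sig2 = 5 m, 75% isopleths, 20-m departure buffer, 999 permutations,
pairwise |r| <= 0.6 and VIF < 10 for the constraint matrix, items kept when
present in at least 3 feces, and the spring/summer/fall season bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = ["PipelineConfig", "validate_config", "load_config"]


@dataclass
class PipelineConfig:
    # input paths (a study directory as written by synthetic.write_study)
    gps: str = "gps.csv"
    landcover: str = "landcover.geojson"
    scats: str = "scats_long.csv"
    sieve_fractions: str = "sieve_fractions.csv"
    correction_factors: str = "correction_factors.csv"
    traits: str = "traits.csv"
    sites: str = "sites.csv"
    out_dir: str = "pipeline_out"
    # parameters
    pdop_max: float = 10.0
    sig2: float = 5.0
    isopleth_level: float = 0.75
    buffer_m: float = 20.0
    grid_cell_m: float = 10.0
    time_steps: int = 100
    gap_tolerance: float = 1.5
    sig1_search: tuple[float, float] = (0.5, 2000.0)
    window_candidates: list[tuple[float, float]] = field(
        default_factory=lambda: [(float(a), float(a + 6)) for a in range(0, 19, 2)]
    )
    n_perm: int = 999
    r_max: float = 0.6
    vif_max: float = 10.0
    min_feces: int = 3
    seed: int = 0

    def resolve(self, base: str | Path) -> "PipelineConfig":
        """Return a copy with input paths resolved against a study dir."""
        base = Path(base)
        kw = asdict(self)
        for key in (
            "gps",
            "landcover",
            "scats",
            "sieve_fractions",
            "correction_factors",
            "traits",
            "sites",
        ):
            kw[key] = str(base / kw[key])
        kw["sig1_search"] = tuple(kw["sig1_search"])
        kw["window_candidates"] = [tuple(w) for w in kw["window_candidates"]]
        return PipelineConfig(**kw)


def validate_config(cfg: PipelineConfig, check_paths: bool = True) -> list[str]:
    """Every violated invariant is reported at once (no fail-fast)."""
    errors: list[str] = []
    if not cfg.pdop_max > 0:
        errors.append(f"pdop_max must be > 0 (got {cfg.pdop_max})")
    if cfg.sig2 < 0:
        errors.append(f"sig2 must be >= 0 (got {cfg.sig2})")
    if not 0 < cfg.isopleth_level < 1:
        errors.append(f"isopleth_level must be in (0,1) (got {cfg.isopleth_level})")
    if not cfg.buffer_m > 0:
        errors.append(f"buffer_m must be > 0 (got {cfg.buffer_m})")
    if not cfg.grid_cell_m > 0:
        errors.append(f"grid_cell_m must be > 0 (got {cfg.grid_cell_m})")
    if cfg.time_steps < 2:
        errors.append(f"time_steps must be >= 2 (got {cfg.time_steps})")
    if cfg.gap_tolerance < 1:
        errors.append(f"gap_tolerance must be >= 1 (got {cfg.gap_tolerance})")
    lo, hi = cfg.sig1_search
    if not 0 < lo < hi:
        errors.append(f"sig1_search must satisfy 0 < lo < hi (got {cfg.sig1_search})")
    for w in cfg.window_candidates:
        if not (0 <= w[0] < w[1] <= 24):
            errors.append(f"window candidate {w} outside [0, 24] or inverted")
    if cfg.n_perm < 99:
        errors.append(f"n_perm must be >= 99 (got {cfg.n_perm})")
    if not 0 < cfg.r_max <= 1:
        errors.append(f"r_max must be in (0,1] (got {cfg.r_max})")
    if not cfg.vif_max > 1:
        errors.append(f"vif_max must be > 1 (got {cfg.vif_max})")
    if cfg.min_feces < 1:
        errors.append(f"min_feces must be >= 1 (got {cfg.min_feces})")
    if check_paths:
        for key in (
            "gps",
            "landcover",
            "scats",
            "sieve_fractions",
            "correction_factors",
            "traits",
            "sites",
        ):
            p = getattr(cfg, key)
            if not Path(p).exists():
                errors.append(f"input path missing: {key} = {p}")
    return errors


def load_config(path) -> PipelineConfig:
    """Read a JSON config file; unknown keys are rejected."""
    with open(path) as fh:
        data = json.load(fh)
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    if "sig1_search" in data:
        data["sig1_search"] = tuple(data["sig1_search"])
    if "window_candidates" in data:
        data["window_candidates"] = [tuple(w) for w in data["window_candidates"]]
    return PipelineConfig(**data)
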
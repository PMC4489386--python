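"""Link scat sites to movement and habitat.

A scat site's departure point is the earliest GPS fix inside a 20-m buffer
around the site (fix precision is ~10 m); backward Brownian-bridge 75%
regions behind that fix, restricted to a candidate ingestion-to-excretion
window, are dissolved into one region whose habitat composition becomes the
site's constraint-matrix row. Scanning candidate windows by the proportion
of diet variance the habitat matrix explains in a CCA selects the
gastrointestinal transit window; diet groups for the per-group analyses come
from the trait ordination's significant categorical vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.ops import unary_union

from .bbmm import BridgeParams, backward_ellipses, bridge_density, isopleth_polygon
from .cca import CcaResult, EnvfitResult, cca_fit, drop_collinear
from .landcover import (
    CoverageError,
    HabitatComposition,
    LandCoverMap,
    composition_in_polygon,
)
from .telemetry import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ScatSite",
    "WindowScanResult",
    "departure_point",
    "site_habitat_row",
    "window_scan",
    "default_candidate_windows",
    "define_diet_groups",
    "DEFAULT_GROUPS",
]


@dataclass
class ScatSite:
    """One scat collection location (feces within a 10-m radius)."""

    site_id: str
    animal_id: str
    x: float
    y: float
    collection_date: object = None
    scat_ids: list[str] = field(default_factory=list)


@dataclass
class DeparturePoint:
    index: int
    distance_m: float
    within_buffer: bool


def departure_point(
    site: ScatSite, trajectory: Trajectory, buffer_m: float = 20.0
) -> DeparturePoint:
    """Earliest fix within ``buffer_m`` of the site; if none, the nearest
    fix overall, flagged ``within_buffer=False`` (distance reported)."""
    if buffer_m <= 0:
        raise ValueError("buffer_m must be positive")
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    if trajectory.animal_id != site.animal_id:
        raise ValueError(
            f"trajectory {trajectory.animal_id} does not belong to site "
            f"animal {site.animal_id}"
        )
    xy = trajectory.xy()
    d = np.hypot(xy[:, 0] - site.x, xy[:, 1] - site.y)
    inside = np.where(d <= buffer_m)[0]
    if len(inside):
        i = int(inside[0])  # fixes are time-ordered: first inside = earliest
        return DeparturePoint(index=i, distance_m=float(d[i]), within_buffer=True)
    i = int(np.argmin(d))
    warnings.warn(
        f"no fix within {buffer_m} m of site {site.site_id}; nearest is "
        f"{d[i]:.1f} m away",
        stacklevel=2,
    )
    return DeparturePoint(index=i, distance_m=float(d[i]), within_buffer=False)


def site_habitat_row(
    site: ScatSite,
    trajectory: Trajectory,
    window: tuple[float, float],
    params: BridgeParams,
    lcmap: LandCoverMap,
    buffer_m: float = 20.0,
    level: float = 0.75,
    cell: float = 10.0,
    time_steps: int = 100,
) -> HabitatComposition | None:
    """Composition of the union of the site's backward-window 75% regions.

    Ellipses are dissolved into a single region before one composition is
    computed (the union, not an average of per-bridge compositions).
    Returns None, with a log entry, when no bridge is eligible.
    """
    dep = departure_point(site, trajectory, buffer_m=buffer_m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        be = backward_ellipses(
            trajectory,
            dep.index,
            window,
            params,
            level=level,
            cell=cell,
            time_steps=time_steps,
        )
    if not be.polygons:
        logger.info(
            "site %s: no eligible bridges in window %s", site.site_id, window
        )
        return None
    merged = unary_union([p.geometry for p in be.polygons])
    try:
        return composition_in_polygon(lcmap, merged)
    except CoverageError:
        logger.info(
            "site %s: window %s region falls outside the mapped extent",
            site.site_id, window,
        )
        return None


def default_candidate_windows(
    min_width_h: float = 4.0,
    max_h: float = 24.0,
    step_h: float = 2.0,
) -> list[tuple[float, float]]:
    """All contiguous (h_from, h_to) windows on a 2-h lattice within
    [0, max_h] with width >= min_width_h."""
    edges = np.arange(0.0, max_h + step_h / 2, step_h)
    return [
        (float(a), float(b))
        for a in edges
        for b in edges
        if b - a >= min_width_h
    ]


@dataclass
class WindowScanResult:
    """Per-window explained-variance table and the selected transit window."""

    table: pd.DataFrame  # columns: h_from, h_to, prop_explained_first2, n_sites
    best_window: tuple[float, float]

    def to_json_dict(self) -> dict:
        return {
            "best_window": list(self.best_window),
            "windows": self.table.to_dict(orient="records"),
        }


def _sites_from_frame(sites: pd.DataFrame | Sequence[ScatSite]) -> list[ScatSite]:
    if isinstance(sites, pd.DataFrame):
        return [
            ScatSite(
                site_id=str(r["site_id"]),
                animal_id=str(r["animal_id"]),
                x=float(r["x"]),
                y=float(r["y"]),
                collection_date=r.get("date"),
            )
            for _, r in sites.iterrows()
        ]
    return list(sites)


def window_scan(
    sites: pd.DataFrame | Sequence[ScatSite],
    trajectories: Mapping[str, Trajectory],
    site_diets: pd.DataFrame,
    candidate_windows: Sequence[tuple[float, float]],
    params: BridgeParams,
    lcmap: LandCoverMap,
    buffer_m: float = 20.0,
    level: float = 0.75,
    cell: float = 10.0,
    time_steps: int = 100,
    r_max: float = 0.6,
    vif_max: float = 10.0,
    max_lookback_h: float = 24.0,
) -> WindowScanResult:
    """Select the transit window maximizing the diet variance explained by
    the first two CCA axes of the habitat-in-window constraint.

    Per-step bridge isopleths are computed once per site over the full
    lookback and reused across windows. Windows with fewer usable sites than
    constraint variables + 2 are skipped with a reason. Ties prefer the
    narrower window, then the earlier h_from. Deterministic given inputs.
    """
    if len(candidate_windows) < 2:
        if len(candidate_windows) == 1:
            w = tuple(candidate_windows[0])
            # single candidate: best by construction
            return WindowScanResult(
                table=pd.DataFrame(
                    [{"h_from": w[0], "h_to": w[1], "prop_explained_first2": np.nan,
                      "n_sites": len(site_diets), "note": "single candidate"}]
                ),
                best_window=w,
            )
        raise ValueError("need at least one candidate window")
    site_list = _sites_from_frame(sites)

    # cache: per site, isopleth polygon + end lag for every step in lookback
    cache: dict[str, list[tuple[float, object]]] = {}
    for site in site_list:
        traj = trajectories[site.animal_id]
        dep = departure_point(site, traj, buffer_m=buffer_m)
        entries: list[tuple[float, object]] = []
        dep_t = traj.fixes[dep.index].timestamp
        for i in range(dep.index):
            a, b = traj.fixes[i], traj.fixes[i + 1]
            end_lag = (dep_t - b.timestamp).total_seconds() / 3600.0
            start_lag = (dep_t - a.timestamp).total_seconds() / 3600.0
            if end_lag < 0 or start_lag > max_lookback_h:
                continue
            if traj.gap_flags[i]:
                continue
            ud = bridge_density(a, b, params, cell=cell, time_steps=time_steps)
            entries.append((end_lag, isopleth_polygon(ud, level=level).geometry))
        cache[site.site_id] = entries

    rows = []
    for h_from, h_to in candidate_windows:
        comps = {}
        for site in site_list:
            geoms = [
                g for lag, g in cache[site.site_id] if h_from <= lag <= h_to
            ]
            if not geoms:
                continue
            try:
                comps[site.site_id] = composition_in_polygon(
                    lcmap, unary_union(geoms)
                ).as_series()
            except CoverageError:
                continue  # region off the mapped extent: site unusable here
        if not comps:
            rows.append(
                {"h_from": h_from, "h_to": h_to, "prop_explained_first2": np.nan,
                 "n_sites": 0, "note": "no usable sites"}
            )
            continue
        X = pd.DataFrame(comps).T
        X = X.loc[:, X.std() > 0]
        common = [s for s in site_diets.index if s in X.index]
        X = X.loc[common]
        Y = site_diets.loc[common]
        try:
            X, _ = drop_collinear(X, r_max=r_max, vif_max=vif_max)
        except ValueError:
            pass
        if len(common) < X.shape[1] + 2:
            rows.append(
                {"h_from": h_from, "h_to": h_to, "prop_explained_first2": np.nan,
                 "n_sites": len(common),
                 "note": f"only {len(common)} sites for {X.shape[1]} variables"}
            )
            continue
        try:
            res = cca_fit(Y, X)
            prop = res.prop_explained_first2
        except (ValueError, np.linalg.LinAlgError) as exc:
            rows.append(
                {"h_from": h_from, "h_to": h_to, "prop_explained_first2": np.nan,
                 "n_sites": len(common), "note": str(exc)}
            )
            continue
        rows.append(
            {"h_from": h_from, "h_to": h_to, "prop_explained_first2": prop,
             "n_sites": len(common), "note": ""}
        )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["prop_explained_first2"])
    if valid.empty:
        raise ValueError("no candidate window produced a usable CCA")
    # tie-break: narrower window, then earlier start
    top = valid[
        valid["prop_explained_first2"]
        >= valid["prop_explained_first2"].max() - 1e-12
    ].copy()
    top["width"] = top["h_to"] - top["h_from"]
    top = top.sort_values(by=["width", "h_from"])
    best_window = (float(top.iloc[0]["h_from"]), float(top.iloc[0]["h_to"]))
    return WindowScanResult(table=table, best_window=best_window)


DEFAULT_GROUPS = {
    "with_cubs": "females_cubs",
    "with_yearlings": "females_yearlings",
    "lone": "lone_bears",
}

CATEGORICAL_TRAITS = ("sex", "reproductive_status")


def define_diet_groups(
    envfit_result: EnvfitResult | None,
    traits: pd.DataFrame,
    alpha: float = 0.05,
    override: Mapping[str, str] | None = None,
) -> pd.Series:
    """Map each animal to a diet group.

    Groups are the combinations of the categorical traits whose envfit
    vectors (dummy-coded) are significant at ``alpha``. With reproductive
    status significant this reproduces the three field groups (females with
    cubs, females with yearlings, lone bears of both sexes). With nothing
    significant a single group is used, with a warning. ``override`` maps
    animal_id to group and short-circuits everything.
    """
    traits = traits.set_index("animal_id") if "animal_id" in traits.columns else traits
    if override is not None:
        return pd.Series({a: override[a] for a in traits.index}, name="group")
    sig_vars: list[str] = []
    if envfit_result is not None:
        sig_vars = envfit_result.significant(alpha)
    sig_traits = [
        t
        for t in CATEGORICAL_TRAITS
        if t in traits.columns
        and any(str(v).startswith(f"{t}=") or str(v) == t for v in sig_vars)
    ]
    if "reproductive_status" in sig_traits:
        # the three field groups: lone bears of both sexes stay pooled even
        # when sex is also significant
        return traits["reproductive_status"].map(DEFAULT_GROUPS).rename("group")
    if "sex" in sig_traits:
        return traits["sex"].map({"M": "males", "F": "females"}).rename("group")
    warnings.warn("no significant categorical trait; using a single diet group")
    return pd.Series("all", index=traits.index, name="group")
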
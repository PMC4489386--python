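"""End-to-end orchestration: telemetry -> diet -> trait CCA -> window scan
-> per-group habitat/diet CCA, with a checksum manifest.

Each stage only reads earlier stages' outputs; every random step draws from
a stage-specific substream derived from the single config seed, so stages
are independently reproducible. Reruns with the same seed produce identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import bbmm, cca, landcover, linkage, scatdiet, telemetry
from .config import PipelineConfig, validate_config

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "stage_rng", "site_diet_matrix", "trait_design"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream: the stage name is hashed into the
    seed sequence so stages can be rerun in isolation."""
    digest = hashlib.sha256(stage.encode()).digest()
    stage_key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, stage_key]))


def site_diet_matrix(
    scats: list[scatdiet.SievedScat],
    factors: dict[str, float],
    min_feces: int = 3,
    include_cubs: bool = False,
):
    """Scat-level corrected profiles -> per-site mean matrix (sites x items),
    scat-level presence counts, rare items dropped. Cub scats are excluded
    from inference unless asked for."""
    profiles: dict[str, list[pd.Series]] = {}
    presence: dict[str, int] = {}
    site_dates: dict[str, object] = {}
    site_animals: dict[str, str] = {}
    n_used = 0
    for scat in scats:
        if scat.is_cub and not include_cubs:
            continue
        raw = scatdiet.scat_raw_composition(scat)
        prof = scatdiet.apply_correction_factors(raw, factors)
        profiles.setdefault(scat.site_id, []).append(prof)
        site_dates[scat.site_id] = scat.collection_date
        site_animals[scat.site_id] = scat.animal_id
        for item in prof.index[prof > 0]:
            presence[item] = presence.get(item, 0) + 1
        n_used += 1
    site_rows = {
        site: scatdiet.site_diet(profs) for site, profs in profiles.items()
    }
    matrix = pd.DataFrame(site_rows).T.fillna(0.0).sort_index()
    matrix, dropped = scatdiet.filter_rare_items(matrix, presence, min_feces)
    return matrix, presence, dropped, site_dates, site_animals, n_used


def trait_design(traits: pd.DataFrame) -> pd.DataFrame:
    """Numeric trait matrix: dummy-coded sex and reproductive status plus
    age, weight, body condition."""
    t = traits.set_index("animal_id") if "animal_id" in traits.columns else traits
    X = pd.DataFrame(index=t.index)
    if "sex" in t:
        X["sex=M"] = (t["sex"] == "M").astype(float)
    if "reproductive_status" in t:
        for level in ("with_cubs", "with_yearlings"):
            X[f"reproductive_status={level}"] = (
                t["reproductive_status"] == level
            ).astype(float)
    for col in ("age", "weight", "body_condition"):
        if col in t:
            X[col] = t[col].astype(float)
    return X


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict (also written to
    ``out_dir/manifest.json``). Halts on the first failing stage, leaving
    earlier outputs in place."""
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "telemetry"
    try:
        # --- telemetry ---
        report = telemetry.read_gps_fixes(cfg.gps)
        kept = telemetry.filter_fixes(report.fixes, pdop_max=cfg.pdop_max)
        trajs: dict[str, telemetry.Trajectory] = {}
        by_animal: dict[str, list] = {}
        for f in kept:
            by_animal.setdefault(f.animal_id, []).append(f)
        for aid, fx in by_animal.items():
            trajs[aid] = telemetry.segment_trajectory(
                fx, gap_tolerance=cfg.gap_tolerance
            )
        qc = telemetry.qc_report(report, kept, trajs)
        (out / "qc_telemetry.json").write_text(json.dumps(qc, indent=1))

        # --- movement parameters ---
        stage = "sig1_estimation"
        sig1_rows = []
        for aid, traj in trajs.items():
            try:
                est = bbmm.estimate_sig1(
                    traj, sig2=cfg.sig2, search_interval=cfg.sig1_search
                )
                sig1_rows.append(
                    {
                        "animal_id": aid,
                        "sig1": est.value,
                        "n_triples": est.n_triples,
                        "at_boundary": est.at_boundary,
                    }
                )
            except ValueError as exc:
                sig1_rows.append(
                    {"animal_id": aid, "sig1": np.nan, "n_triples": 0,
                     "at_boundary": False, "note": str(exc)}
                )
        sig1_table = pd.DataFrame(sig1_rows)
        sig1_table.to_csv(out / "sig1_per_animal.csv", index=False)

        # --- diet ---
        stage = "scatdiet"
        scats = scatdiet.read_scat_observations(cfg.scats, cfg.sieve_fractions)
        factors = (
            pd.read_csv(cfg.correction_factors)
            .set_index("item")["factor"]
            .to_dict()
        )
        (matrix, presence, dropped, site_dates, site_animals, n_scats) = (
            site_diet_matrix(scats, factors, min_feces=cfg.min_feces)
        )
        matrix.to_csv(out / "site_diet_matrix.csv")
        seasonal = scatdiet.seasonal_population_summary(matrix, site_dates)
        seasonal.to_csv(out / "seasonal_summary.csv", index=False)

        # --- trait CCA and diet groups ---
        stage = "trait_cca"
        traits = pd.read_csv(cfg.traits)
        Xt_animal = trait_design(traits)
        strata = pd.Series(site_animals).loc[matrix.index]
        Xt = Xt_animal.loc[strata.values].set_axis(matrix.index)
        Xt = Xt.loc[:, Xt.std() > 0]
        Xt_pruned, prune_trail = cca.drop_collinear(
            Xt, r_max=cfg.r_max, vif_max=cfg.vif_max
        )
        trait_result = None
        envfit_res = None
        try:
            trait_result = cca.cca_fit(matrix, Xt_pruned)
            rng = stage_rng(cfg.seed, "trait_cca")
            axis_table = cca.axis_significance(
                matrix, Xt_pruned, strata.values, n_perm=cfg.n_perm,
                seed=rng, max_axes=2,
            )
            envfit_res = cca.envfit_vectors(
                trait_result.site_scores, Xt, strata.values,
                n_perm=cfg.n_perm, seed=stage_rng(cfg.seed, "trait_envfit"),
            )
            trait_out = {
                "prop_explained_first2": trait_result.prop_explained_first2,
                "constrained_eigenvalues": trait_result.constrained_eigenvalues.tolist(),
                "total_inertia": trait_result.total_inertia,
                "axis_tests": axis_table.to_dict(orient="records"),
                "envfit": envfit_res.table.to_dict(orient="records"),
                "pruned": prune_trail,
            }
        except (ValueError, np.linalg.LinAlgError) as exc:
            trait_out = {"error": str(exc)}
        (out / "trait_cca.json").write_text(
            json.dumps(trait_out, indent=1, default=float)
        )
        groups = linkage.define_diet_groups(envfit_res, traits)
        groups.to_csv(out / "diet_groups.csv")

        # --- window scan ---
        stage = "window_scan"
        lcmap = landcover.landcover_from_geojson(cfg.landcover)
        sites = pd.read_csv(cfg.sites)
        sites = sites[sites["site_id"].isin(matrix.index)]
        sig1_map = sig1_table.set_index("animal_id")["sig1"].to_dict()
        sig1_default = float(np.nanmedian(list(sig1_map.values())))
        # one bridge parameter set per animal (annual individual estimate)
        scan = None
        scan_out: dict = {}
        try:
            params = bbmm.BridgeParams(sig1=sig1_default, sig2=cfg.sig2)
            scan = linkage.window_scan(
                sites,
                trajs,
                matrix,
                cfg.window_candidates,
                params,
                lcmap,
                buffer_m=cfg.buffer_m,
                level=cfg.isopleth_level,
                cell=cfg.grid_cell_m,
                time_steps=cfg.time_steps,
                r_max=cfg.r_max,
                vif_max=cfg.vif_max,
            )
            scan.table.to_csv(out / "window_scan.csv", index=False)
            scan_out = scan.to_json_dict()
        except (ValueError, KeyError) as exc:
            scan_out = {"error": str(exc)}
        (out / "window_scan.json").write_text(
            json.dumps(scan_out, indent=1, default=float)
        )

        # --- per-group habitat/diet CCA at the selected window ---
        stage = "group_cca"
        group_results = {}
        if scan is not None:
            best = scan.best_window
            params = bbmm.BridgeParams(sig1=sig1_default, sig2=cfg.sig2)
            site_groups = strata.map(groups.to_dict())
            for gname in sorted(site_groups.dropna().unique()):
                g_sites = site_groups.index[site_groups == gname]
                sub_sites = sites[sites["site_id"].isin(g_sites)]
                comps = {}
                for site in linkage._sites_from_frame(sub_sites):
                    comp = linkage.site_habitat_row(
                        site, trajs[site.animal_id], best, params, lcmap,
                        buffer_m=cfg.buffer_m, level=cfg.isopleth_level,
                        cell=cfg.grid_cell_m, time_steps=cfg.time_steps,
                    )
                    if comp is not None:
                        comps[site.site_id] = comp.as_series()
                if not comps:
                    group_results[gname] = {"error": "no usable sites"}
                    continue
                Xh = pd.DataFrame(comps).T
                Xh = Xh.loc[:, Xh.std() > 0]
                Yg = matrix.loc[Xh.index]
                Yg = Yg.loc[:, Yg.sum() > 0]
                try:
                    Xh, _ = cca.drop_collinear(Xh, cfg.r_max, cfg.vif_max)
                    while Xh.shape[1] + 1 >= len(Xh.index) and Xh.shape[1] > 1:
                        Xh = Xh.iloc[:, :-1]
                    res = cca.cca_fit(Yg, Xh)
                    env = cca.envfit_vectors(
                        res.site_scores, Xh,
                        strata.loc[Xh.index].values,
                        n_perm=cfg.n_perm,
                        seed=stage_rng(cfg.seed, f"group_envfit_{gname}"),
                    )
                    group_results[gname] = {
                        "n_sites": len(Xh.index),
                        "prop_explained_first2": res.prop_explained_first2,
                        "constrained_eigenvalues": res.constrained_eigenvalues.tolist(),
                        "total_inertia": res.total_inertia,
                        "envfit": env.table.to_dict(orient="records"),
                    }
                except (ValueError, np.linalg.LinAlgError) as exc:
                    group_results[gname] = {"error": str(exc)}
        (out / "group_cca.json").write_text(
            json.dumps(group_results, indent=1, default=float)
        )

        # --- descriptive site counts (field-report arithmetic) ---
        stage = "descriptives"
        desc = group_site_summary(
            pd.Series(site_animals).loc[matrix.index],
            traits.set_index("animal_id"),
        )
        desc.to_csv(out / "sites_per_bear.csv", index=False)

    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise

    manifest = {
        "config": {**asdict(cfg)},
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def group_site_summary(
    site_animals: pd.Series, traits: pd.DataFrame
) -> pd.DataFrame:
    """Sites-per-bear arithmetic by group: n bears, n sites, mean, SD, min,
    max (counting zero-site collared bears where present in traits)."""
    group_col = (
        "group" if "group" in traits.columns else "reproductive_status"
    )
    counts = site_animals.value_counts()
    rows = []
    all_counts = []
    for gname, sub in traits.groupby(group_col):
        per_bear = np.array([counts.get(a, 0) for a in sub.index], dtype=float)
        all_counts.extend(per_bear)
        rows.append(
            {
                "group": gname,
                "n_bears": len(sub),
                "n_sites": int(per_bear.sum()),
                "mean": float(per_bear.mean()),
                "sd": float(per_bear.std(ddof=1)) if len(per_bear) > 1 else 0.0,
                "min": int(per_bear.min()),
                "max": int(per_bear.max()),
            }
        )
    ac = np.array(all_counts)
    rows.append(
        {
            "group": "total",
            "n_bears": len(ac),
            "n_sites": int(ac.sum()),
            "mean": float(ac.mean()),
            "sd": float(ac.std(ddof=1)) if len(ac) > 1 else 0.0,
            "min": int(ac.min()),
            "max": int(ac.max()),
        }
    )
    return pd.DataFrame(rows)
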
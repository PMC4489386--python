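#!/usr/bin/env python
"""Trait ordination, diet groups, and per-group habitat-diet CCA.

Relates site diet profiles to individual traits (sex, reproductive status,
age, weight, body condition) with individuals as permutation strata, groups
bears by the significant categorical trait vectors, then fits one
habitat-diet CCA per group at the transit window selected by the scan.
Writes results/trait_cca.json and results/group_cca.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from bearlink import cca, landcover, scatdiet, telemetry
from bearlink.bbmm import BridgeParams
from bearlink.linkage import define_diet_groups, site_habitat_row, _sites_from_frame
from bearlink.pipeline import site_diet_matrix, stage_rng, trait_design

RESULTS = Path(__file__).resolve().parents[1] / "results"
STUDY = Path(__file__).resolve().parents[1] / "scratch" / "study"
SEED = 7


def main() -> None:
    study = STUDY
    scats = scatdiet.read_scat_observations(
        study / "scats_long.csv", study / "sieve_fractions.csv"
    )
    factors = (
        pd.read_csv(study / "correction_factors.csv")
        .set_index("item")["factor"].to_dict()
    )
    matrix, _, _, _, site_animals, _ = site_diet_matrix(scats, factors)
    traits = pd.read_csv(study / "traits.csv")
    strata = pd.Series(site_animals).loc[matrix.index]

    Xt = trait_design(traits).loc[strata.values].set_axis(matrix.index)
    Xt = Xt.loc[:, Xt.std() > 0]
    Xt_pruned, trail = cca.drop_collinear(Xt)
    res = cca.cca_fit(matrix, Xt_pruned)
    env = cca.envfit_vectors(res.site_scores, Xt, strata.values, n_perm=999,
                             seed=stage_rng(SEED, "trait_envfit"))
    (RESULTS / "trait_cca.json").write_text(json.dumps({
        "prop_explained_first2": res.prop_explained_first2,
        "envfit": env.table.to_dict(orient="records"),
        "pruned": trail,
    }, indent=1, default=float))
    print(f"trait CCA: first two axes explain "
          f"{100 * res.prop_explained_first2:.1f}% of diet inertia")
    sig = env.significant(0.05)
    print(f"significant trait vectors (p < 0.05): {sig if sig else 'none'}")

    groups = define_diet_groups(env, traits)
    print(f"diet groups: {sorted(groups.unique())}")

    best = tuple(json.loads((RESULTS / "window_scan.json").read_text())["best_window"])
    lcmap = landcover.landcover_from_geojson(study / "landcover.geojson")
    sites = pd.read_csv(study / "sites.csv")
    sites = sites[sites["site_id"].isin(matrix.index)]
    sig1 = pd.read_csv(RESULTS / "sig1_per_animal.csv")["sig1"].median()
    params = BridgeParams(sig1=float(sig1), sig2=5.0)

    report = telemetry.read_gps_fixes(study / "gps.csv")
    kept = telemetry.filter_fixes(report.fixes)
    by_animal: dict[str, list] = {}
    for f in kept:
        by_animal.setdefault(f.animal_id, []).append(f)
    trajs = {a: telemetry.segment_trajectory(fx) for a, fx in by_animal.items()}

    site_groups = strata.map(groups.to_dict())
    out = {}
    for gname in sorted(site_groups.dropna().unique()):
        g_sites = sites[sites["site_id"].isin(site_groups.index[site_groups == gname])]
        comps = {}
        for site in _sites_from_frame(g_sites):
            comp = site_habitat_row(site, trajs[site.animal_id], best, params,
                                    lcmap, cell=20.0, time_steps=50)
            if comp is not None:
                comps[site.site_id] = comp.as_series()
        if len(comps) < 4:
            out[gname] = {"note": f"only {len(comps)} usable sites"}
            continue
        Xh = pd.DataFrame(comps).T
        Xh = Xh.loc[:, Xh.std() > 0]
        Xh, _ = cca.drop_collinear(Xh)
        while Xh.shape[1] + 1 >= len(Xh.index) and Xh.shape[1] > 1:
            Xh = Xh.iloc[:, :-1]
        resg = cca.cca_fit(matrix.loc[Xh.index], Xh)
        envg = cca.envfit_vectors(
            resg.site_scores, Xh, strata.loc[Xh.index].values, n_perm=999,
            seed=stage_rng(SEED, f"group_envfit_{gname}"),
        )
        out[gname] = {
            "n_sites": len(Xh.index),
            "prop_explained_first2": resg.prop_explained_first2,
            "significant_habitat_vectors": envg.significant(0.05),
        }
        print(f"{gname}: {len(Xh.index)} sites, first two axes explain "
              f"{100 * resg.prop_explained_first2:.1f}%; significant habitat "
              f"vectors: {envg.significant(0.05) or 'none'}")
    (RESULTS / "group_cca.json").write_text(json.dumps(out, indent=1, default=float))


if __name__ == "__main__":
    main()
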
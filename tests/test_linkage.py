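"""Departure points, backward-window habitat rows, window scan mechanics
and diet-group definition."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from bearlink.bbmm import BridgeParams
from bearlink.cca import EnvfitResult
from bearlink.landcover import LandCoverMap
from bearlink.linkage import (
    ScatSite,
    default_candidate_windows,
    define_diet_groups,
    departure_point,
    site_habitat_row,
)
from bearlink.telemetry import segment_trajectory

from .conftest import fix_at

PARAMS = BridgeParams(sig1=300.0, sig2=5.0)


def track(positions, animal="b1"):
    return segment_trajectory(
        [fix_at(2 * i, x, y, animal=animal) for i, (x, y) in enumerate(positions)]
    )


class TestDeparturePoint:
    def test_earliest_fix_within_buffer_wins(self):
        # distances from site: 25, 8, 5 m in time order -> the 8-m fix
        traj = track([(25, 0), (8, 0), (5, 0)])
        site = ScatSite("s1", "b1", 0.0, 0.0)
        dep = departure_point(site, traj, buffer_m=20.0)
        assert dep.index == 1
        assert dep.within_buffer

    def test_single_close_fix(self):
        traj = track([(3, 0), (500, 0)])
        dep = departure_point(ScatSite("s1", "b1", 0.0, 0.0), traj)
        assert dep.index == 0

    def test_nearest_fallback_with_warning(self):
        traj = track([(100, 0), (40, 0), (70, 0)])
        with pytest.warns(UserWarning, match="nearest"):
            dep = departure_point(ScatSite("s1", "b1", 0.0, 0.0), traj)
        assert dep.index == 1
        assert not dep.within_buffer
        assert dep.distance_m == pytest.approx(40.0)

    def test_wrong_animal_rejected(self):
        traj = track([(3, 0), (5, 0)], animal="other")
        with pytest.raises(ValueError, match="belong"):
            departure_point(ScatSite("s1", "b1", 0.0, 0.0), traj)


def two_stand_map(split_x=50_000.0, size=100_000.0):
    """West half Conifer, east half Swamp."""
    return LandCoverMap(
        stands=[box(-size, -size, split_x, size), box(split_x, -size, size, size)],
        categories=["Conifer", "Swamp"],
    )


class TestSiteHabitatRow:
    def test_single_ellipse_equals_its_composition(self):
        lcmap = two_stand_map()
        positions = [(400.0 * i, 0.0) for i in range(8)]
        traj = track(positions)
        site = ScatSite("s1", "b1", *positions[-1])
        comp = site_habitat_row(site, traj, (10, 12), PARAMS, lcmap, cell=20)
        assert comp is not None
        assert comp.area_props["Conifer"] == pytest.approx(1.0)

    def test_union_of_coincident_ellipses_is_idempotent(self):
        # the track traverses the same segment out and back: the two bridges
        # cover the same region, so dissolving both adds no area
        lcmap = two_stand_map()
        positions = [(0, 0), (400, 0), (0, 0)] + [
            (10_000.0 + 400 * i, 0.0) for i in range(6)
        ]
        traj = track(positions)  # departure fix at t = 16 h
        site = ScatSite("s1", "b1", 12_000.0, 0.0)
        one = site_habitat_row(site, traj, (13, 15), PARAMS, lcmap, cell=20)
        both = site_habitat_row(site, traj, (11, 15), PARAMS, lcmap, cell=20)
        # out and back bridges cover the same region up to one boundary-cell
        # ring (the cumulative-mass cutoff lands on different tie cells)
        assert one.polygon_area_km2 == pytest.approx(
            both.polygon_area_km2, rel=0.01
        )

    def test_disjoint_equal_ellipses_average_compositions(self):
        # two far-apart identical-shape bridges, one all-Conifer and one
        # all-Swamp; the transit between them is a flagged 6-h gap, so the
        # dissolved region is their 50/50 union
        lcmap = two_stand_map(split_x=25_000.0)
        fixes = [
            fix_at(0, 0, 0),
            fix_at(2, 400, 0),            # Conifer bridge, ends lag 14
            fix_at(8, 50_000, 0),         # flagged gap: skipped
            fix_at(10, 50_400, 0),        # Swamp bridge, ends lag 6
            fix_at(12, 50_000, 5_000),
            fix_at(14, 50_000, 10_000),
            fix_at(16, 50_000, 20_000),
        ]
        traj = segment_trajectory(fixes)
        site = ScatSite("s1", "b1", 50_000.0, 20_000.0)
        c_only = site_habitat_row(site, traj, (13, 15), PARAMS, lcmap, cell=20)
        s_only = site_habitat_row(site, traj, (5, 7), PARAMS, lcmap, cell=20)
        both = site_habitat_row(site, traj, (5, 15), PARAMS, lcmap, cell=20)
        assert c_only.area_props["Conifer"] == pytest.approx(1.0)
        assert s_only.area_props["Swamp"] == pytest.approx(1.0)
        assert both.area_props["Conifer"] == pytest.approx(0.5, abs=0.02)
        assert both.area_props["Swamp"] == pytest.approx(0.5, abs=0.02)

    def test_union_area_monotone_in_window_width(self):
        lcmap = two_stand_map()
        positions = [(400.0 * i, 100.0 * (i % 3)) for i in range(10)]
        traj = track(positions)
        site = ScatSite("s1", "b1", *positions[-1])
        areas = []
        for hi in (12, 14, 16, 18):
            comp = site_habitat_row(site, traj, (10, hi), PARAMS, lcmap, cell=20)
            areas.append(comp.polygon_area_km2)
        assert all(a <= b + 1e-12 for a, b in zip(areas, areas[1:]))

    def test_no_eligible_bridges_returns_none(self):
        lcmap = two_stand_map()
        traj = track([(0, 0), (400, 0), (800, 0)])
        site = ScatSite("s1", "b1", 800.0, 0.0)
        assert site_habitat_row(site, traj, (10, 16), PARAMS, lcmap, cell=20) is None


class TestCandidateWindows:
    def test_default_family_is_the_two_hour_lattice(self):
        wins = default_candidate_windows()
        assert (10.0, 16.0) in wins
        assert all(b - a >= 4.0 and 0 <= a < b <= 24 for a, b in wins)
        # all bounds on the 2-h lattice
        assert all(a % 2 == 0 and b % 2 == 0 for a, b in wins)


def _envfit_table(sig_vars):
    rows = []
    for v in ["sex=M", "reproductive_status=with_cubs",
              "reproductive_status=with_yearlings", "age", "weight"]:
        rows.append(
            {"variable": v, "dcos1": 1.0, "dcos2": 0.0, "r2": 0.5,
             "p_value": 0.01 if v in sig_vars else 0.6}
        )
    return EnvfitResult(table=pd.DataFrame(rows), n_perm=999)


TRAITS = pd.DataFrame(
    {
        "animal_id": ["b1", "b2", "b3", "b4"],
        "sex": ["M", "F", "F", "F"],
        "reproductive_status": ["lone", "with_cubs", "with_yearlings", "lone"],
    }
)


class TestDefineDietGroups:
    def test_significant_reproductive_status_gives_three_groups(self):
        env = _envfit_table({"reproductive_status=with_cubs"})
        groups = define_diet_groups(env, TRAITS)
        assert groups["b2"] == "females_cubs"
        assert groups["b3"] == "females_yearlings"
        assert groups["b1"] == groups["b4"] == "lone_bears"
        assert groups.nunique() == 3

    def test_nothing_significant_gives_single_group(self):
        env = _envfit_table(set())
        with pytest.warns(UserWarning, match="single"):
            groups = define_diet_groups(env, TRAITS)
        assert groups.nunique() == 1

    def test_sex_only_gives_two_groups(self):
        env = _envfit_table({"sex=M"})
        groups = define_diet_groups(env, TRAITS)
        assert groups["b1"] == "males"
        assert set(groups[["b2", "b3", "b4"]]) == {"females"}

    def test_override_short_circuits(self):
        groups = define_diet_groups(
            None, TRAITS, override={a: "g" for a in TRAITS["animal_id"]}
        )
        assert (groups == "g").all()

    def test_group_structured_diets_recover_three_groups(self):
        # generator truth: item boosts differ by reproductive status, so the
        # trait ordination should flag the categorical vectors and the three
        # field groups should emerge
        from bearlink.cca import cca_fit, envfit_vectors
        from bearlink.pipeline import site_diet_matrix, trait_design
        from bearlink.synthetic import SimConfig, generate_study

        cfg = SimConfig(n_days=20)
        study = generate_study(cfg, seed=17, noise_sd=0.0)
        matrix, _, _, _, site_animals, _ = site_diet_matrix(
            study.scats, cfg.correction_factors
        )
        strata = pd.Series(site_animals).loc[matrix.index]
        Xt = trait_design(study.bears).loc[strata.values].set_axis(matrix.index)
        Xt = Xt.loc[:, Xt.std() > 0]
        res = cca_fit(matrix, Xt[["sex=M", "reproductive_status=with_cubs",
                                  "reproductive_status=with_yearlings"]])
        env = envfit_vectors(res.site_scores, Xt, strata.values,
                             n_perm=199, seed=11)
        groups = define_diet_groups(env, study.bears)
        assert set(groups.unique()) == {
            "females_cubs", "females_yearlings", "lone_bears"
        }
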
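"""Constrained correspondence analysis: eigenstructure, permutation
inference and constraint pruning, checked against independent oracles."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.linalg
from scipy.stats import chi2_contingency

from bearlink.cca import (
    axis_significance,
    cca_fit,
    drop_collinear,
    envfit_vectors,
    permute_within_strata,
    total_inertia,
)


def brute_force_cca_eigenvalues(Y, X):
    """Independent oracle: form the chi-square residual matrix and solve the
    constrained eigenproblem densely via an explicit hat matrix and
    scipy.linalg.eigh on Q_fit' Q_fit (no SVD of the fit path)."""
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    total = Y.sum()
    P = Y / total
    r, c = P.sum(axis=1), P.sum(axis=0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    Xc = X - r @ X
    Xs = np.sqrt(r)[:, None] * Xc
    H = Xs @ scipy.linalg.inv(Xs.T @ Xs) @ Xs.T
    QH = H @ Q
    lam = scipy.linalg.eigh(QH.T @ QH, eigvals_only=True)[::-1]
    return lam[lam > 1e-10], float((Q**2).sum())


class TestCcaFit:
    def test_total_inertia_of_2x2_table_is_chisq_over_n(self):
        Y = np.array([[10.0, 20.0], [30.0, 15.0]])
        chi2 = chi2_contingency(Y, correction=False)[0]
        assert total_inertia(Y) == pytest.approx(chi2 / Y.sum(), abs=1e-12)

    def test_cca_total_inertia_agrees_with_chisq_helper(self):
        rng = np.random.default_rng(31)
        Y = rng.integers(1, 30, size=(6, 4)).astype(float)
        X = rng.normal(size=(6, 2))
        assert cca_fit(Y, X).total_inertia == pytest.approx(
            total_inertia(Y), abs=1e-12
        )

    def test_eigenvalues_match_bruteforce_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            Y = rng.integers(1, 30, size=(6, 4)).astype(float)
            X = rng.normal(size=(6, 2))
            res = cca_fit(Y, X)
            lam_oracle, inertia_oracle = brute_force_cca_eigenvalues(Y, X)
            assert np.allclose(
                res.constrained_eigenvalues, lam_oracle[: len(res.constrained_eigenvalues)],
                atol=1e-8,
            )
            assert res.total_inertia == pytest.approx(inertia_oracle, abs=1e-10)

    def test_eigenvalue_partition_sums_to_total_inertia(self):
        rng = np.random.default_rng(7)
        Y = rng.integers(1, 30, size=(10, 6)).astype(float)
        X = rng.normal(size=(10, 3))
        res = cca_fit(Y, X)
        s = res.constrained_eigenvalues.sum() + res.unconstrained_eigenvalues.sum()
        assert s == pytest.approx(res.total_inertia, abs=1e-8)

    def test_saturated_constraint_recovers_ca_axis(self):
        # X = exact copy of the first CA axis: the first constrained
        # eigenvalue equals the first unconstrained eigenvalue of plain CA
        rng = np.random.default_rng(13)
        Y = rng.integers(1, 30, size=(8, 5)).astype(float)
        P = Y / Y.sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, S, _ = np.linalg.svd(Q, full_matrices=False)
        ca_lam1 = S[0] ** 2
        X = (U[:, 0] / np.sqrt(r)).reshape(-1, 1)  # CA site scores, axis 1
        res = cca_fit(Y, X)
        assert res.constrained_eigenvalues[0] == pytest.approx(ca_lam1, abs=1e-10)

    def test_prop_explained_invariant_to_scaling_y(self):
        rng = np.random.default_rng(21)
        Y = rng.integers(1, 30, size=(7, 4)).astype(float)
        X = rng.normal(size=(7, 2))
        p1 = cca_fit(Y, X).prop_explained_first2
        p2 = cca_fit(Y * 3.7, X).prop_explained_first2
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_negative_y_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            cca_fit(np.array([[1.0, -1.0], [1.0, 1.0], [2.0, 1.0]]),
                    np.array([[0.0], [1.0], [2.0]]))

    def test_rank_deficient_x_rejected(self):
        rng = np.random.default_rng(3)
        Y = rng.integers(1, 20, size=(6, 4)).astype(float)
        x = rng.normal(size=6)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            cca_fit(Y, X)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_vegan_reference(self, tmp_path):
        rng = np.random.default_rng(42)
        Y = rng.integers(1, 20, size=(8, 5)).astype(float)
        X = rng.normal(size=(8, 3))
        yp, xp = tmp_path / "Y.csv", tmp_path / "X.csv"
        np.savetxt(yp, Y, delimiter=",")
        np.savetxt(xp, X, delimiter=",")
        script = (
            'suppressMessages(library(vegan));'
            f'Y <- as.matrix(read.csv("{yp}", header=FALSE));'
            f'X <- as.matrix(read.csv("{xp}", header=FALSE));'
            'm <- cca(Y ~ X);'
            'cat(m$CCA$eig, "\\n"); cat(m$tot.chi, "\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        lines = out.stdout.strip().splitlines()
        vegan_eig = np.array([float(v) for v in lines[0].split()])
        vegan_total = float(lines[1])
        res = cca_fit(Y, X)
        assert np.allclose(res.constrained_eigenvalues, vegan_eig, atol=1e-6)
        assert res.total_inertia == pytest.approx(vegan_total, abs=1e-6)


def _assoc_data(n_per=4, n_ind=4, seed=0):
    """Sites nested in individuals; row profiles shift deterministically and
    monotonically with x, so the observed ordering is the best possible."""
    rng = np.random.default_rng(seed)
    n = n_per * n_ind
    x = rng.normal(size=n)
    strata = np.repeat([f"i{k}" for k in range(n_ind)], n_per)
    u = (x - x.min()) / (x.max() - x.min())
    Y = np.column_stack(
        [1 + 29 * u, 30 - 29 * u, np.full(n, 10.0), np.full(n, 5.0)]
    )
    return Y, x.reshape(-1, 1), strata


class TestAxisSignificance:
    def test_perfect_association_attains_p_floor(self):
        Y, X, strata = _assoc_data(seed=5)
        out = axis_significance(Y, X, strata, n_perm=999, seed=1, max_axes=1)
        assert out["p_value"].iloc[0] == pytest.approx(1 / 1000)

    def test_same_seed_reproduces_p_values(self):
        Y, X, strata = _assoc_data(seed=6)
        a = axis_significance(Y, X, strata, n_perm=199, seed=42, max_axes=1)
        b = axis_significance(Y, X, strata, n_perm=199, seed=42, max_axes=1)
        pd.testing.assert_frame_equal(a, b)

    def test_invariant_to_strata_relabeling(self):
        Y, X, strata = _assoc_data(seed=7)
        relabel = {"i0": "zebra", "i1": "yak", "i2": "x", "i3": "w"}
        # permutation structure depends on positions, not labels
        a = axis_significance(Y, X, strata, n_perm=199, seed=3, max_axes=1)
        b = axis_significance(
            Y, X, np.array([relabel[s] for s in strata]), n_perm=199, seed=3,
            max_axes=1,
        )
        assert a["p_value"].iloc[0] == b["p_value"].iloc[0]

    def test_all_singleton_strata_undefined(self):
        Y, X, _ = _assoc_data(seed=8)
        with pytest.raises(ValueError, match="singleton"):
            axis_significance(Y, X, np.arange(len(Y)), n_perm=199, seed=0)


class TestPermuteWithinStrata:
    def test_only_exchanges_within_strata(self):
        rng = np.random.default_rng(0)
        strata = np.array(["a", "a", "b", "b", "b", "c"])
        for _ in range(20):
            idx = permute_within_strata(rng, strata)
            assert (strata[idx] == strata).all()
            assert sorted(idx) == list(range(6))


class TestEnvfit:
    def _scores(self, n=12, seed=1):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n, 2)), np.repeat(["i1", "i2", "i3"], n // 3)

    def test_copy_of_axis_one_is_perfect_fit(self):
        scores, strata = self._scores()
        env = pd.DataFrame({"v": scores[:, 0]})
        res = envfit_vectors(scores, env, strata, n_perm=99, seed=0)
        row = res.table.iloc[0]
        assert row["r2"] == pytest.approx(1.0, abs=1e-10)
        assert abs(row["dcos1"]) == pytest.approx(1.0, abs=1e-8)
        assert row["p_value"] == pytest.approx(1 / 100)

    def test_orthogonal_variable_has_zero_r2(self):
        # build v exactly orthogonal to the intercept and both score axes
        rng = np.random.default_rng(9)
        Qm, _ = np.linalg.qr(
            np.column_stack([np.ones(12), rng.normal(size=(12, 3))])
        )
        scores = Qm[:, 1:3]
        env = pd.DataFrame({"v": Qm[:, 3]})
        res = envfit_vectors(scores, env, np.repeat(["a", "b", "c"], 4),
                             n_perm=99, seed=0)
        assert res.table["r2"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_r2_matches_multivariate_regression_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            scores = rng.normal(size=(15, 2))
            v = rng.normal(size=15)
            res = envfit_vectors(
                scores, pd.DataFrame({"v": v}), np.repeat(["a", "b", "c"], 5),
                n_perm=99, seed=0,
            )
            A = np.column_stack([np.ones(15), scores])
            beta, _, _, _ = np.linalg.lstsq(A, v, rcond=None)
            resid = v - A @ beta
            oracle = 1 - resid @ resid / ((v - v.mean()) ** 2).sum()
            assert res.table["r2"].iloc[0] == pytest.approx(oracle, abs=1e-10)

    def test_individual_level_trait_uses_between_strata_permutation(self):
        # a variable constant within every stratum cannot move under
        # within-stratum shuffling; exchanging whole individuals restores a
        # valid, non-degenerate null (p attains the floor under perfect fit)
        rng = np.random.default_rng(23)
        strata = np.repeat([f"i{k}" for k in range(8)], 3)
        trait_by_ind = rng.normal(size=8)
        v = np.repeat(trait_by_ind, 3)
        scores = np.column_stack([v, rng.normal(size=24)])  # axis1 == trait
        res = envfit_vectors(scores, pd.DataFrame({"sex": v}), strata,
                             n_perm=199, seed=0)
        row = res.table.iloc[0]
        assert row["r2"] == pytest.approx(1.0, abs=1e-10)
        assert row["p_value"] == pytest.approx(1 / 200)

    def test_constant_variable_not_fittable(self):
        scores, strata = self._scores()
        res = envfit_vectors(scores, pd.DataFrame({"v": np.ones(12)}),
                             strata, n_perm=99, seed=0)
        assert np.isnan(res.table["r2"].iloc[0])


class TestDropCollinear:
    def test_duplicated_column_drops_exactly_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=20)})
        reduced, trail = drop_collinear(X)
        assert reduced.shape[1] == 2
        assert "c" in reduced.columns
        assert len(trail) == 1

    def test_only_one_member_of_correlated_pair_dropped(self):
        # pairwise r = {0.7 between a,b; ~0.1 elsewhere}: only one of a,b goes
        rng = np.random.default_rng(2)
        n = 400
        a = rng.normal(size=n)
        b = 0.7 * a + np.sqrt(1 - 0.49) * rng.normal(size=n)
        c = rng.normal(size=n)
        X = pd.DataFrame({"a": a, "b": b, "c": c})
        reduced, trail = drop_collinear(X, r_max=0.6)
        assert reduced.shape[1] == 2
        assert "c" in reduced.columns
        assert trail[0]["rule"] == "pairwise_r"

    def test_orthonormal_columns_untouched(self):
        Qm, _ = np.linalg.qr(np.random.default_rng(3).normal(size=(30, 4)))
        X = pd.DataFrame(Qm, columns=list("abcd"))
        reduced, trail = drop_collinear(X)
        assert list(reduced.columns) == list("abcd")
        assert trail == []
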
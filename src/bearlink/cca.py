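"""Constrained correspondence analysis with strata-restricted permutations.

CCA ordinates a nonnegative site-by-item response matrix Y in chi-square
geometry while constraining site scores to linear combinations of the
columns of an explanatory matrix X. With P = Y / grand total, row masses r,
column masses c, the standardized residual matrix is

    Q_ij = (P_ij - r_i c_j) / sqrt(r_i c_j).

Q's rows are projected (row-weighted by r) onto the column space of X; the
singular values of the fitted part squared are the constrained eigenvalues,
those of the residual the unconstrained ones, and total inertia = sum Q^2
(the table's chi-square statistic over its grand total).

Inference respects repeated measures on individuals: permutation nulls only
exchange rows within strata (one stratum per individual), both for the
sequential by-axis pseudo-F tests and for post-hoc environmental-vector
fitting (envfit). p = (1 + exceedances) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CcaResult",
    "EnvfitResult",
    "total_inertia",
    "cca_fit",
    "axis_significance",
    "envfit_vectors",
    "drop_collinear",
    "permute_within_strata",
]

EIG_TOL = 1e-10


@dataclass
class CcaResult:
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    total_inertia: float
    site_scores: np.ndarray  # n x k, linear-combination scores, principal scaling
    item_scores: np.ndarray  # m x k
    variable_scores: np.ndarray  # p x k, correlations of X columns with axes
    row_weights: np.ndarray
    site_ids: list = field(default_factory=list)
    item_ids: list = field(default_factory=list)
    variable_ids: list = field(default_factory=list)

    @property
    def prop_explained_first2(self) -> float:
        k = min(2, len(self.constrained_eigenvalues))
        return float(self.constrained_eigenvalues[:k].sum() / self.total_inertia)


def _as_matrix(a, name: str):
    if isinstance(a, pd.DataFrame):
        return a.to_numpy(dtype=float), list(a.index), list(a.columns)
    arr = np.asarray(a, dtype=float)
    return arr, list(range(arr.shape[0])), list(range(arr.shape[1]))


def _chi_square_pieces(Y: np.ndarray):
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    return Q, r, c


def total_inertia(Y) -> float:
    """Total inertia of a nonnegative table: sum of squared standardized
    chi-square residuals, i.e. the table's chi-square statistic divided by
    its grand total."""
    Ym, _, _ = _as_matrix(Y, "Y")
    if Ym.min() < 0:
        raise ValueError("Y must be nonnegative")
    Q, _, _ = _chi_square_pieces(Ym)
    return float((Q**2).sum())


def _weighted_design(X: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row-weight-centred design scaled by sqrt(r): Xs = sqrt(W)(X - mean_w)."""
    mean_w = r @ X
    Xc = X - mean_w
    return np.sqrt(r)[:, None] * Xc


def cca_fit(Y, X, Z=None) -> CcaResult:
    """Fit a (partial) constrained correspondence analysis.

    Y: sites x items nonnegative; X: sites x variables; optional Z: sites x
    conditioning variables partialled out of both X and the response before
    the constrained step. Returns eigenvalues, scores and total inertia.
    """
    Ym, site_ids, item_ids = _as_matrix(Y, "Y")
    Xm, _, var_ids = _as_matrix(X, "X")
    if Ym.min() < 0:
        raise ValueError("Y must be nonnegative")
    if (Ym.sum(axis=1) <= 0).any():
        raise ValueError("every Y row must have positive total")
    if not np.isfinite(Xm).all():
        raise ValueError("X must be finite")
    if np.any(Xm.std(axis=0) == 0):
        const = [var_ids[j] for j in range(Xm.shape[1]) if Xm[:, j].std() == 0]
        raise ValueError(f"constant constraint columns: {const}")
    n, m = Ym.shape
    if Ym.shape[0] != Xm.shape[0]:
        raise ValueError("Y and X must have aligned rows")

    Q, r, c = _chi_square_pieces(Ym)
    total_inertia = float((Q**2).sum())

    Xs = _weighted_design(Xm, r)
    if Z is not None:
        Zm, _, _ = _as_matrix(Z, "Z")
        Zs = _weighted_design(Zm, r)
        Qz, _, _, _ = np.linalg.lstsq(Zs, Q, rcond=None)
        Q = Q - Zs @ Qz
        Xz, _, _, _ = np.linalg.lstsq(Zs, Xs, rcond=None)
        Xs = Xs - Zs @ Xz

    rank = np.linalg.matrix_rank(Xs)
    if rank < Xs.shape[1]:
        raise np.linalg.LinAlgError(
            "constraint matrix is rank-deficient after weighting/centring; "
            "prune collinear columns first"
        )
    if n <= Xs.shape[1] + 1:
        raise ValueError("need n sites > n constraint variables + 1")

    beta, _, _, _ = np.linalg.lstsq(Xs, Q, rcond=None)
    Q_fit = Xs @ beta
    Q_res = Q - Q_fit

    U, S, Vt = np.linalg.svd(Q_fit, full_matrices=False)
    lam_c = S**2
    keep_c = lam_c > EIG_TOL
    lam_c, U, S, Vt = lam_c[keep_c], U[:, keep_c], S[keep_c], Vt[keep_c]

    _, S_r, _ = np.linalg.svd(Q_res, full_matrices=False)
    lam_u = S_r**2
    lam_u = lam_u[lam_u > EIG_TOL]

    with np.errstate(divide="ignore", invalid="ignore"):
        site_scores = (U * S) / np.sqrt(r)[:, None]
        item_scores = (Vt.T * S) / np.sqrt(c)[:, None]

    # variable scores: weighted correlation of raw X columns with site scores
    k = site_scores.shape[1]
    var_scores = np.zeros((Xm.shape[1], k))
    for j in range(Xm.shape[1]):
        xj = Xm[:, j] - r @ Xm[:, j]
        for a in range(k):
            sa = site_scores[:, a] - r @ site_scores[:, a]
            denom = np.sqrt((r * xj**2).sum() * (r * sa**2).sum())
            var_scores[j, a] = (r * xj * sa).sum() / denom if denom > 0 else 0.0

    return CcaResult(
        constrained_eigenvalues=lam_c,
        unconstrained_eigenvalues=np.sort(lam_u)[::-1],
        total_inertia=total_inertia,
        site_scores=site_scores,
        item_scores=item_scores,
        variable_scores=var_scores,
        row_weights=r,
        site_ids=site_ids,
        item_ids=item_ids,
        variable_ids=var_ids,
    )


def permute_within_strata(
    rng: np.random.Generator, strata: np.ndarray
) -> np.ndarray:
    """Index permutation exchanging positions only within each stratum
    (Fisher-Yates per stratum via rng.permutation)."""
    strata = np.asarray(strata)
    idx = np.arange(len(strata))
    for s in np.unique(strata):
        pos = np.where(strata == s)[0]
        idx[pos] = pos[rng.permutation(len(pos))]
    return idx


def _strata_array(strata, site_ids) -> np.ndarray:
    if isinstance(strata, Mapping):
        return np.array([strata[s] for s in site_ids])
    return np.asarray(strata)


def axis_significance(
    Y,
    X,
    strata,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    max_axes: int | None = None,
) -> pd.DataFrame:
    """Sequential by-axis permutation tests with individuals as strata.

    Axis k is tested by the pseudo-F of its eigenvalue over residual inertia
    with the previous constrained axes partialled out (their site scores act
    as conditioning covariates); the null distribution permutes Y rows only
    within strata. Returns a table of eigenvalue, F and p per axis.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    Ym, site_ids, _ = _as_matrix(Y, "Y")
    Xm, _, _ = _as_matrix(X, "X")
    st = _strata_array(strata, site_ids)
    if len(st) != Ym.shape[0]:
        raise ValueError("strata must cover every site")
    sizes = pd.Series(st).value_counts()
    if (sizes == 1).all():
        raise ValueError("all strata are singletons: permutation test undefined")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    base = cca_fit(Ym, Xm)
    n_axes = len(base.constrained_eigenvalues)
    if max_axes is not None:
        n_axes = min(n_axes, max_axes)

    def axis_stat(Yp: np.ndarray, Z: np.ndarray | None, k_prev: int) -> float:
        """Pseudo-F of the leading constrained axis given conditioning Z."""
        res = cca_fit(Yp, Xm, Z=Z)
        if len(res.constrained_eigenvalues) == 0:
            return 0.0
        lam1 = res.constrained_eigenvalues[0]
        resid = res.total_inertia - res.constrained_eigenvalues.sum()
        df = Ym.shape[0] - Xm.shape[1] - 1 - k_prev
        # a saturated fit (resid ~ 0) gets a large finite F, not inf
        return float(lam1 / max(resid / max(df, 1), 1e-300))

    rows = []
    for k in range(n_axes):
        Z = base.site_scores[:, :k] if k > 0 else None
        obs = axis_stat(Ym, Z, k)
        exceed = 0
        for _ in range(n_perm):
            idx = permute_within_strata(rng, st)
            try:
                stat = axis_stat(Ym[idx], Z, k)
            except (ValueError, np.linalg.LinAlgError):
                stat = 0.0
            if stat >= obs:
                exceed += 1
        rows.append(
            {
                "axis": k + 1,
                "eigenvalue": float(base.constrained_eigenvalues[k]),
                "pseudo_F": obs,
                "p_value": (1 + exceed) / (1 + n_perm),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EnvfitResult:
    table: pd.DataFrame  # variable, dcos1, dcos2, r2, p_value
    n_perm: int

    def significant(self, alpha: float = 0.05) -> list[str]:
        t = self.table
        return list(t.loc[(t["p_value"] < alpha) & t["r2"].notna(), "variable"])


def _fit_one_vector(scores: np.ndarray, v: np.ndarray):
    """OLS of variable v on the 2-D (unweighted) score space; returns
    (r2, unit direction)."""
    A = np.column_stack([np.ones(len(v)), scores])
    coef, _, _, _ = np.linalg.lstsq(A, v, rcond=None)
    fitted = A @ coef
    ss_tot = ((v - v.mean()) ** 2).sum()
    if ss_tot <= 0:
        return np.nan, np.array([np.nan, np.nan])
    r2 = 1.0 - ((v - fitted) ** 2).sum() / ss_tot
    b = coef[1:]
    norm = np.linalg.norm(b)
    direction = b / norm if norm > 0 else np.zeros_like(b)
    return float(max(0.0, r2)), direction


def _permute_between_strata(
    rng: np.random.Generator, strata: np.ndarray, v: np.ndarray
) -> np.ndarray:
    """Exchange whole strata: permute the per-stratum values of a variable
    that is constant within each stratum, then broadcast back to rows.
    The null treats individuals, not observations, as exchangeable."""
    uniq, inv = np.unique(strata, return_inverse=True)
    level_vals = np.array([v[inv == k][0] for k in range(len(uniq))])
    return level_vals[rng.permutation(len(uniq))][inv]


def envfit_vectors(
    site_scores: np.ndarray,
    env,
    strata,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> EnvfitResult:
    """Post-hoc vector fitting of environmental/trait variables onto
    ordination axes 1-2, with permutation significance that respects
    repeated measures on individuals.

    Site-level variables (habitat composition rows) are permuted within
    strata. A variable constant within every stratum (an individual trait
    such as sex) cannot move under that scheme, so whole strata are
    exchanged instead: the individual is the permutation unit either way.
    Constant variables are reported as not fittable (r2 = NaN, p = NaN).
    """
    scores = np.asarray(site_scores, dtype=float)[:, :2]
    Em, row_ids, var_ids = _as_matrix(env, "env")
    if scores.shape[0] != Em.shape[0]:
        raise ValueError("scores and env must have aligned rows")
    st = _strata_array(strata, row_ids)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows = []
    for j, name in enumerate(var_ids):
        v = Em[:, j]
        if np.std(v) == 0:
            rows.append(
                {
                    "variable": name,
                    "dcos1": np.nan,
                    "dcos2": np.nan,
                    "r2": np.nan,
                    "p_value": np.nan,
                }
            )
            continue
        within_sd = pd.Series(v).groupby(pd.Series(st)).std(ddof=0)
        stratum_constant = bool((within_sd.fillna(0.0) == 0.0).all())
        r2, direction = _fit_one_vector(scores, v)
        exceed = 0
        for _ in range(n_perm):
            if stratum_constant:
                vp = _permute_between_strata(rng, st, v)
            else:
                vp = v[permute_within_strata(rng, st)]
            r2p, _ = _fit_one_vector(scores, vp)
            if r2p >= r2:
                exceed += 1
        rows.append(
            {
                "variable": name,
                "dcos1": direction[0],
                "dcos2": direction[1],
                "r2": r2,
                "p_value": (1 + exceed) / (1 + n_perm),
            }
        )
    return EnvfitResult(table=pd.DataFrame(rows), n_perm=n_perm)


def drop_collinear(
    X: pd.DataFrame, r_max: float = 0.6, vif_max: float = 10.0
) -> tuple[pd.DataFrame, list[dict]]:
    """Constraint-matrix pruning: drop one member of every pair with
    |Pearson r| > r_max (the member with larger mean absolute correlation to
    the rest; ties drop the later column), then drop max-VIF columns until
    all VIF < vif_max. Returns the reduced matrix and an audit trail."""
    if X.shape[1] < 2:
        return X.copy(), []
    X = X.copy()
    trail: list[dict] = []
    order = {c: i for i, c in enumerate(X.columns)}

    while X.shape[1] >= 2:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        r = corr.loc[worst]
        if r <= r_max:
            break
        a, b = worst
        mean_a = corr.loc[a].drop([a, b]).mean() if X.shape[1] > 2 else 0.0
        mean_b = corr.loc[b].drop([a, b]).mean() if X.shape[1] > 2 else 0.0
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = a if order[a] > order[b] else b
        trail.append({"dropped": drop, "rule": "pairwise_r", "r": float(r)})
        X = X.drop(columns=[drop])

    def vifs(df: pd.DataFrame) -> pd.Series:
        out = {}
        M = df.to_numpy(dtype=float)
        for j, col in enumerate(df.columns):
            y = M[:, j]
            others = np.delete(M, j, axis=1)
            A = np.column_stack([np.ones(len(y)), others])
            coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ coef
            ss_tot = ((y - y.mean()) ** 2).sum()
            r2 = 1 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
            out[col] = 1.0 / max(1.0 - r2, 1e-12)
        return pd.Series(out)

    while X.shape[1] >= 2:
        v = vifs(X)
        if v.max() < vif_max:
            break
        drop = v.idxmax()
        trail.append({"dropped": drop, "rule": "vif", "vif": float(v.max())})
        X = X.drop(columns=[drop])

    if X.shape[1] < 1:
        raise ValueError("collinearity pruning removed every column")
    return X, trail
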
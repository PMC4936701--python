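"""Multilocus environmental association: RDA, pRDA, and MRM.

Redundancy analysis (RDA) regresses a population x response matrix (here
arcsine-square-root allele frequencies: one column per allele per locus
for multi-allelic markers, one column per locus for biallelic ones) on
predictor sets such as climate variables or trend-surface geography, and
eigen-decomposes the fitted values.  Partial RDA first residualizes both
response and predictors on a conditioning set.  Model significance is a
permutation ANOVA on the pseudo-F; explained variance is reported both
raw (R^2 = constrained/total inertia) and bias-adjusted (Ezekiel).
Variance partitioning splits the explainable variance into
climate-independent, geography-independent, and confounded fractions.

Multiple regression on distance matrices (MRM) performs OLS on the
vectorized lower triangles of distance matrices, with significance by
joint row/column permutation of the response matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import DistanceMatrix
from .climate_prep import TrendSurface

__all__ = [
    "RDAResult",
    "MRMResult",
    "VariancePartition",
    "rda",
    "prda",
    "stepwise_select",
    "permutation_anova",
    "adjusted_r2",
    "conditional_adjusted_r2",
    "variance_partition",
    "mrm",
    "mrm_conditional",
]


def _as_matrix(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


@dataclass
class RDAResult:
    eigenvalues: np.ndarray  # constrained axes, descending
    total_inertia: float
    constrained_inertia: float
    r2: float
    n: int
    m: int  # predictor rank (conditioning columns excluded)
    q: int = 0  # conditioning rank
    conditioning: str = ""
    site_scores: np.ndarray | None = None
    # internal matrices retained for permutation tests
    _Y: np.ndarray | None = field(default=None, repr=False)
    _X: np.ndarray | None = field(default=None, repr=False)

    @property
    def r2_adj(self) -> float:
        return adjusted_r2(self)


@dataclass
class MRMResult:
    coefficients: dict[str, float]
    intercept: float
    r2: float
    f: float
    p: float | None


@dataclass
class VariancePartition:
    r2_climate: float
    r2_geography: float
    r2_joint: float
    climate_independent: float  # fraction of explainable variance
    geography_independent: float
    confounded: float


def _fit_projection(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return X @ beta


def rda(Y, X) -> RDAResult:
    """Redundancy analysis of centered Y on centered X.

    Constrained axes are the eigenpairs of Yhat' Yhat / (n-1) where Yhat
    is the OLS projection of Y on X; R^2 is the ratio of constrained to
    total inertia.
    """
    Y = _as_matrix(Y)
    X = _as_matrix(X)
    n = Y.shape[0]
    if X.shape[0] != n:
        raise ValueError("Y and X row counts differ")
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    m = np.linalg.matrix_rank(Xc)
    if m == 0:
        raise ValueError("predictor matrix has rank 0")
    if n <= m + 1:
        import warnings

        warnings.warn("more predictors than residual df; fit is saturated",
                      stacklevel=2)
    Yhat = _fit_projection(Yc, Xc)
    total = float((Yc**2).sum()) / (n - 1)
    constrained = float((Yhat**2).sum()) / (n - 1)
    u, s, _ = np.linalg.svd(Yhat, full_matrices=False)
    eig = (s**2) / (n - 1)
    eig = eig[eig > 1e-12 * max(eig[0] if eig.size else 1.0, 1.0)]
    return RDAResult(
        eigenvalues=eig,
        total_inertia=total,
        constrained_inertia=constrained,
        r2=constrained / total if total > 0 else np.nan,
        n=n,
        m=m,
        site_scores=u[:, : len(eig)] * s[: len(eig)],
        _Y=Yc,
        _X=Xc,
    )


def prda(Y, X, Z) -> RDAResult:
    """Partial RDA: effect of X on Y after removing the conditioning set Z."""
    Y = _as_matrix(Y)
    X = _as_matrix(X)
    Z = _as_matrix(Z)
    Zc = Z - Z.mean(axis=0)
    Xc = X - X.mean(axis=0)
    q = np.linalg.matrix_rank(Zc)
    # X residualized on Z must retain some signal
    Xr = Xc - _fit_projection(Xc, Zc)
    if np.linalg.matrix_rank(Xr, tol=1e-10) == 0:
        raise ValueError("conditioning set spans the predictors; nothing to test")
    Yc = Y - Y.mean(axis=0)
    Yr = Yc - _fit_projection(Yc, Zc)
    res = rda(Yr, Xr)
    res.q = q
    res.conditioning = f"rank-{q} conditioning set"
    return res


def adjusted_r2(res: RDAResult) -> float:
    """Ezekiel's adjustment 1 - (1-R^2)(n-1)/(n-m-1)."""
    dof = res.n - res.m - res.q - 1
    if dof <= 0:
        return float("nan")
    # for partial models the adjustment uses the df left after conditioning
    return 1.0 - (1.0 - res.r2) * (res.n - res.q - 1) / dof


def conditional_adjusted_r2(Y, X, Z) -> float:
    """Adjusted R^2 of X given Z by difference of nested unconditional fits."""
    XZ = np.column_stack([_as_matrix(X), _as_matrix(Z)])
    return adjusted_r2(rda(Y, XZ)) - adjusted_r2(rda(Y, Z))


def permutation_anova(
    res: RDAResult,
    n_perm: int = 9_999,
    by: str = "model",
    seed: int | None = None,
) -> tuple[float, float] | pd.DataFrame:
    """Permutation test of an RDA fit.

    ``by="model"``: pseudo-F = (constrained/df_model)/(residual/df_res)
    with rows of the (already residualized, for partial fits) response
    permuted.  ``by="axis"``: marginal test per constrained axis using the
    axis eigenvalue as statistic.  Returns (F, p) or a per-axis frame.
    """
    if n_perm < 99:
        import warnings

        warnings.warn(f"n_perm = {n_perm} is very low", stacklevel=2)
    Y, X = res._Y, res._X
    if Y is None or X is None:
        raise ValueError("RDAResult lacks stored matrices")
    n = res.n
    df_model = res.m
    df_res = n - res.m - res.q - 1
    resid = max(res.total_inertia - res.constrained_inertia, 0.0)
    f_obs = (
        np.inf
        if resid == 0
        else (res.constrained_inertia / df_model) / (resid / df_res)
    )
    rng = np.random.default_rng(seed)

    def constrained_of(Yp: np.ndarray) -> float:
        Yhat = _fit_projection(Yp, X)
        return float((Yhat**2).sum()) / (n - 1)

    if by == "model":
        count = 0
        for _ in range(n_perm):
            Yp = Y[rng.permutation(n)]
            cp = constrained_of(Yp)
            rp = max(res.total_inertia - cp, 0.0)
            fp = np.inf if rp == 0 else (cp / df_model) / (rp / df_res)
            count += fp >= f_obs - 1e-12
        return f_obs, (1 + count) / (n_perm + 1)
    if by == "axis":
        k = len(res.eigenvalues)
        counts = np.zeros(k)
        for _ in range(n_perm):
            Yp = Y[rng.permutation(n)]
            Yhat = _fit_projection(Yp, X)
            s = np.linalg.svd(Yhat, compute_uv=False)
            eig_p = (s**2) / (n - 1)
            for a in range(k):
                if a < len(eig_p) and eig_p[a] >= res.eigenvalues[a] - 1e-12:
                    counts[a] += 1
        return pd.DataFrame(
            {
                "eigenvalue": res.eigenvalues,
                "p": (1 + counts) / (n_perm + 1),
            },
            index=[f"RDA{i + 1}" for i in range(k)],
        )
    raise ValueError(f"unknown by={by!r}")


def stepwise_select(
    Y,
    candidates: TrendSurface,
    p_in: float = 0.05,
    p_out: float = 0.10,
    n_perm: int = 199,
    seed: int | None = None,
) -> tuple[list[str], list[str]]:
    """Forward-backward selection of trend-surface terms for an RDA.

    At each forward step the candidate with the smallest marginal
    permutation p (given the current model) enters if p <= p_in; at each
    backward step the weakest retained term leaves if p >= p_out.
    Returns (selected terms in entry order, audit trail of actions).
    """
    Y = _as_matrix(Y)
    rng = np.random.default_rng(seed)
    terms = candidates.term_names
    selected: list[str] = []
    trail: list[str] = []

    def marginal_p(term: str, current: list[str]) -> tuple[float, float]:
        X = candidates.terms[[term]].to_numpy()
        if current:
            Z = candidates.terms[current].to_numpy()
            res = prda(Y, X, Z)
        else:
            res = rda(Y, X)
        f, p = permutation_anova(
            res, n_perm=n_perm, by="model", seed=int(rng.integers(2**31 - 1))
        )
        return p, f

    changed = True
    while changed:
        changed = False
        # forward
        best = None
        for term in terms:
            if term in selected:
                continue
            p, f = marginal_p(term, selected)
            if best is None or (p, -f) < (best[1], -best[2]):
                best = (term, p, f)
        if best is not None and best[1] <= p_in:
            selected.append(best[0])
            trail.append(f"+{best[0]} (p={best[1]:.4g})")
            changed = True
        # backward
        if len(selected) > 1:
            worst = None
            for term in selected:
                others = [t for t in selected if t != term]
                p, f = marginal_p(term, others)
                if worst is None or p > worst[1]:
                    worst = (term, p)
            if worst is not None and worst[1] >= p_out:
                selected.remove(worst[0])
                trail.append(f"-{worst[0]} (p={worst[1]:.4g})")
                changed = True
    return selected, trail


def variance_partition(Y, X_clim, X_geo) -> VariancePartition:
    """Partition explainable variance among climate, geography, overlap.

    Fractions are reported relative to the joint R^2 (raw, not adjusted);
    a negative confounded fraction is possible and reported as-is.
    """
    r2_c = rda(Y, X_clim).r2
    r2_g = rda(Y, X_geo).r2
    XZ = np.column_stack([_as_matrix(X_clim), _as_matrix(X_geo)])
    r2_j = rda(Y, XZ).r2
    clim_ind = r2_j - r2_g
    geo_ind = r2_j - r2_c
    confounded = r2_c + r2_g - r2_j
    return VariancePartition(
        r2_climate=r2_c,
        r2_geography=r2_g,
        r2_joint=r2_j,
        climate_independent=clim_ind / r2_j,
        geography_independent=geo_ind / r2_j,
        confounded=confounded / r2_j,
    )


# ---------------------------------------------------------------------------
# MRM


def _lower_triangle(dm: DistanceMatrix, labels: list[str]) -> np.ndarray:
    v = dm.reorder(labels).values
    if np.isnan(v).any():
        raise ValueError(
            "response matrix contains undefined entries (disconnected pairs)"
        )
    il = np.tril_indices(len(labels), -1)
    return v[il]


def mrm(
    d_resp: DistanceMatrix,
    d_preds: list[DistanceMatrix] | DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MRMResult:
    """OLS of the response distance matrix on predictor distance matrices.

    Coefficients are on the original distance scale; the permutation test
    jointly permutes rows and columns of the response matrix and refits.
    """
    if isinstance(d_preds, DistanceMatrix):
        d_preds = [d_preds]
    labels = list(d_resp.labels)
    y = _lower_triangle(d_resp, labels)
    names = [p.name or f"pred{i + 1}" for i, p in enumerate(d_preds)]
    X = np.column_stack(
        [np.ones(len(y))] + [_lower_triangle(p, labels) for p in d_preds]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    m = X.shape[1] - 1
    df_res = len(y) - m - 1
    f = (r2 / m) / ((1 - r2) / df_res) if r2 < 1 else np.inf
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        k = len(labels)
        resp = d_resp.reorder(labels).values
        il = np.tril_indices(k, -1)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(k)
            yp = resp[np.ix_(perm, perm)][il]
            bp, *_ = np.linalg.lstsq(X, yp, rcond=None)
            rp = 1.0 - float(((yp - X @ bp) ** 2).sum()) / float(
                ((yp - yp.mean()) ** 2).sum()
            )
            count += rp >= r2 - 1e-12
        p = (1 + count) / (n_perm + 1)
    return MRMResult(dict(zip(names, beta[1:])), float(beta[0]), r2, float(f), p)


def mrm_conditional(
    d_resp: DistanceMatrix,
    d_cond: DistanceMatrix | list[DistanceMatrix],
    d_pred: DistanceMatrix | list[DistanceMatrix],
    n_perm: int = 999,
    seed: int | None = None,
) -> MRMResult:
    """MRM of the response residualized on conditioning distance matrices.

    The vectorized response is regressed (OLS) on the conditioning
    distances, the residuals are reassembled into a symmetric matrix with
    zero diagonal, and an ordinary MRM against the focal predictor(s) is
    run on that residual matrix.
    """
    if isinstance(d_cond, DistanceMatrix):
        d_cond = [d_cond]
    labels = list(d_resp.labels)
    y = _lower_triangle(d_resp, labels)
    Xc = np.column_stack(
        [np.ones(len(y))] + [_lower_triangle(c, labels) for c in d_cond]
    )
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    k = len(labels)
    mat = np.zeros((k, k))
    il = np.tril_indices(k, -1)
    mat[il] = resid
    mat = mat + mat.T
    # residual "distances" may be negative; the container only requires
    # symmetry and a zero diagonal
    shifted = DistanceMatrix(labels, mat, name=f"{d_resp.name}|conditioned")
    return mrm(shifted, d_pred, n_perm=n_perm, seed=seed)
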
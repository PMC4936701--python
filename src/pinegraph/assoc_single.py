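"""Single-locus environmental association screening.

Per-population frequencies of a focal allele at each biallelic locus are
arcsine-square-root transformed, residualized on spatial trend-surface
predictors to strip geographic/demographic signal, and rank-correlated
(Spearman) with the leading climate principal components.  p-values use
the large-sample t approximation and are converted to step-up q-values
(Benjamini-Hochberg-derived FDR), with q < 0.05 the customary screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .climate_prep import PCAResult, TrendSurface
from .diversity import AlleleFrequencyTable

__all__ = [
    "AssociationRecord",
    "transform_frequencies",
    "spatial_residuals",
    "associate",
    "qvalues",
]


@dataclass
class AssociationRecord:
    locus: str
    axis: str
    rho: float
    p: float
    q: float | None
    detrend: str


def transform_frequencies(aft: AlleleFrequencyTable) -> pd.DataFrame:
    """arcsin(sqrt(p)) of the focal-allele frequency per population x locus.

    The focal allele of a locus is the alphabetically first of its minor
    alleles (ties between exactly-0.5 alleles also resolve alphabetically);
    loci with more than two alleles or no polymorphism are skipped.
    Spearman-based screens are invariant in |rho| to which allele is focal.
    """
    cols: dict[str, np.ndarray] = {}
    for locus in aft.loci:
        alleles = aft.alleles(locus)
        if len(alleles) != 2:
            continue
        # pooled frequency weighting by gene-copy counts
        n = aft.n_genes[locus].to_numpy(dtype=float)
        p0 = np.array([aft.frequency(pop, locus, alleles[0]) for pop in aft.populations])
        pooled0 = float((p0 * n).sum() / n.sum()) if n.sum() else 0.5
        focal = alleles[0] if pooled0 <= 0.5 else alleles[1]
        p = np.array([aft.frequency(pop, locus, focal) for pop in aft.populations])
        cols[locus] = np.arcsin(np.sqrt(np.clip(p, 0.0, 1.0)))
    return pd.DataFrame(cols, index=aft.populations)


def spatial_residuals(
    freq_matrix: pd.DataFrame, predictors: TrendSurface | None
) -> pd.DataFrame:
    """Residuals of each locus column after OLS on spatial predictors.

    ``predictors=None`` just centers the columns (geography ignored).
    Collinear predictor columns are dropped with a warning.
    """
    Y = freq_matrix.to_numpy(dtype=float)
    if predictors is None:
        return freq_matrix - freq_matrix.mean(axis=0)
    X = predictors.terms.loc[freq_matrix.index].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        import warnings

        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-10 * np.abs(np.diag(r)).max()
        warnings.warn(
            f"dropping {int((~keep).sum())} collinear predictor column(s)",
            stacklevel=2,
        )
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid, index=freq_matrix.index, columns=freq_matrix.columns)


def associate(
    residuals: pd.DataFrame,
    pca: PCAResult,
    n_axes: int | None = None,
    detrend: str = "unspecified",
) -> list[AssociationRecord]:
    """Spearman correlation of locus residuals with leading climate PCs.

    Uses the t approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df for
    two-sided p-values.  Degenerate locus columns (all residuals equal)
    are skipped.  q-values are attached across all records.
    """
    n = len(residuals)
    if n < 5:
        raise ValueError("need at least 5 populations")
    if n_axes is None:
        n_axes = max(pca.n_retained, 1)
    axes = pca.scores.columns[:n_axes]
    scores = pca.scores.loc[residuals.index]
    records: list[AssociationRecord] = []
    for locus in residuals.columns:
        y = residuals[locus].to_numpy()
        if np.allclose(y, y[0]):
            continue
        for axis in axes:
            rho = float(stats.spearmanr(y, scores[axis].to_numpy()).statistic)
            if abs(rho) >= 1.0:
                p = 0.0
            else:
                t = rho * np.sqrt((n - 2) / (1 - rho**2))
                p = float(2 * stats.t.sf(abs(t), df=n - 2))
            records.append(AssociationRecord(locus, axis, rho, p, None, detrend))
    qs = qvalues([rec.p for rec in records])
    for rec, q in zip(records, qs):
        rec.q = float(q)
    return records


def qvalues(pvals) -> np.ndarray:
    """Monotone step-up q-values (Benjamini-Hochberg-derived).

    q(i) = min over j >= i of m*p(j)/j on the sorted p-values, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def records_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus": r.locus,
                "axis": r.axis,
                "rho": r.rho,
                "p": r.p,
                "q": r.q,
                "detrend": r.detrend,
            }
            for r in records
        ]
    )
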
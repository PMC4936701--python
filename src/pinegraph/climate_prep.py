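"""Climate-variable preparation and spatial predictors.

Bioclimatic variables are standardized to z-scores, thinned by pairwise
correlation so no retained pair exceeds |r| = 0.80, and summarized by a PCA
on the correlation structure (components with eigenvalue > 1 retained).
Geography enters the association analyses as a cubic trend surface: the
nine monomials of centered longitude (x) and latitude (y) up to total
degree 3.  Climate and geographic distance matrices feed the
distance-based analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ClimateTable, DistanceMatrix, GeoTable

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "PCAResult",
    "TrendSurface",
    "standardize",
    "trim_correlated",
    "climate_pca",
    "build_trend_surface",
    "climate_distance",
    "geographic_distance",
]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    proportion_variance: np.ndarray
    scores: pd.DataFrame  # population x axis
    loadings: pd.DataFrame  # variable x axis
    n_retained: int  # eigenvalue > 1 rule


@dataclass
class TrendSurface:
    """Polynomial spatial predictors from centered coordinates."""

    terms: pd.DataFrame  # population x term, columns named x, y, x^2, ...

    @property
    def term_names(self) -> list[str]:
        return list(self.terms.columns)

    def subset(self, names: list[str]) -> "TrendSurface":
        return TrendSurface(self.terms[list(names)])


def standardize(ct: ClimateTable) -> ClimateTable:
    """Center each variable and scale to unit standard deviation (ddof=1)."""
    sds = ct.table.std(axis=0, ddof=1)
    zero = sds.index[sds == 0].tolist()
    if zero:
        raise ValueError(f"zero-variance climate variables: {zero}")
    z = (ct.table - ct.table.mean(axis=0)) / sds
    return ClimateTable(z, standardized=True)


def trim_correlated(
    ct: ClimateTable, r_limit: float = 0.80
) -> tuple[ClimateTable, list[str]]:
    """Greedily drop variables until all pairwise |Pearson r| < r_limit.

    At each step the most-correlated pair is found and the member with the
    larger mean absolute correlation to all other remaining variables is
    dropped (ties broken toward the later column).  Returns the retained
    table and the ordered list of dropped variable names.
    """
    if not ct.standardized:
        raise ValueError("trim_correlated expects a standardized table")
    cols = list(ct.table.columns)
    if len(cols) < 2:
        import warnings

        warnings.warn("fewer than 2 variables; nothing to trim", stacklevel=2)
        return ct, []
    dropped: list[str] = []
    remaining = cols[:]
    while True:
        corr = ct.table[remaining].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        abs_corr = np.abs(corr)
        i, j = np.unravel_index(np.argmax(abs_corr), abs_corr.shape)
        if abs_corr[i, j] < r_limit:
            break
        # drop the member more correlated with everything else overall
        mean_i = abs_corr[i].sum() / (len(remaining) - 1)
        mean_j = abs_corr[j].sum() / (len(remaining) - 1)
        if mean_j >= mean_i:
            victim = max(i, j) if np.isclose(mean_i, mean_j) else j
        else:
            victim = i
        dropped.append(remaining[victim])
        remaining.pop(victim)
        if len(remaining) < 2:
            break
    return ClimateTable(ct.table[remaining], standardized=True), dropped


def climate_pca(ct: ClimateTable) -> PCAResult:
    """PCA of the variable correlation matrix of a standardized table.

    Scores are the standardized data projected on the eigenvectors.  The
    sign of each loading vector is fixed so its largest-magnitude element
    is positive.  ``n_retained`` counts eigenvalues above 1 (the
    Kaiser rule used to pick climate axes for the single-locus screen).
    """
    if not ct.standardized:
        raise ValueError("climate_pca expects a standardized table")
    X = ct.table.to_numpy()
    n, p = X.shape
    corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(p):
        pivot = np.argmax(np.abs(evecs[:, k]))
        if evecs[pivot, k] < 0:
            evecs[:, k] = -evecs[:, k]
    scores = X @ evecs
    axes = [f"PC{i + 1}" for i in range(p)]
    rank = np.linalg.matrix_rank(corr)
    if rank < p:
        import warnings

        warnings.warn(f"correlation matrix rank-deficient (rank {rank} < {p})",
                      stacklevel=2)
    return PCAResult(
        eigenvalues=evals,
        proportion_variance=evals / evals.sum(),
        scores=pd.DataFrame(scores, index=ct.table.index, columns=axes),
        loadings=pd.DataFrame(evecs, index=ct.table.columns, columns=axes),
        n_retained=int((evals > 1.0).sum()),
    )


def build_trend_surface(geo: GeoTable, degree: int = 3) -> TrendSurface:
    """Monomials of centered longitude/latitude up to ``degree`` (no intercept)."""
    if len(geo.populations) < 3:
        raise ValueError("need at least 3 populations for a trend surface")
    x = geo.table["longitude"].to_numpy(dtype=float)
    y = geo.table["latitude"].to_numpy(dtype=float)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("all populations share one coordinate; surface degenerate")
    x = x - x.mean()
    y = y - y.mean()
    terms: dict[str, np.ndarray] = {}
    for total in range(1, degree + 1):
        for i in range(total, -1, -1):
            j = total - i
            name = _term_name(i, j)
            terms[name] = x**i * y**j
    df = pd.DataFrame(terms, index=geo.table.index)
    df = df - df.mean(axis=0)  # higher-order monomials recentred
    return TrendSurface(df)


def _term_name(i: int, j: int) -> str:
    def power(sym: str, k: int) -> str:
        if k == 0:
            return ""
        return sym if k == 1 else f"{sym}^{k}"

    return power("x", i) + power("y", j)


def climate_distance(ct: ClimateTable) -> DistanceMatrix:
    """Euclidean distance between population rows of a standardized table."""
    if not ct.standardized:
        raise ValueError("climate_distance expects a standardized table")
    X = ct.table.to_numpy()
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(list(ct.table.index), d, name="climate")


def geographic_distance(
    source: GeoTable | TrendSurface, method: str = "great_circle_km"
) -> DistanceMatrix:
    """Pairwise geographic distance.

    ``great_circle_km``: haversine distance on a sphere of radius
    6371.0088 km from a :class:`GeoTable`.  ``euclidean_terms``: Euclidean
    distance over trend-surface predictor columns (the geography actually
    used by the constrained ordinations).
    """
    if method == "great_circle_km":
        if not isinstance(source, GeoTable):
            raise ValueError("great_circle_km requires a GeoTable")
        lon = np.radians(source.table["longitude"].to_numpy())
        lat = np.radians(source.table["latitude"].to_numpy())
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = (
            np.sin(dlat / 2) ** 2
            + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        )
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(source.populations, d, name="geography_km")
    if method == "euclidean_terms":
        if not isinstance(source, TrendSurface):
            raise ValueError("euclidean_terms requires a TrendSurface")
        X = source.terms.to_numpy()
        diff = X[:, None, :] - X[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        return DistanceMatrix(list(source.terms.index), d, name="geography_terms")
    raise ValueError(f"unknown method {method!r}")
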
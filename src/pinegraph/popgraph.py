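"""Population Graphs and conditional genetic distance (cGD).

A Population Graph is a Gaussian-graphical-model view of population
structure.  Individuals are encoded as multilocus allele-dosage vectors,
populations are reduced to their centroid vectors, and the among-population
covariance matrix is recovered from the squared Euclidean distances
between centroids by Gower double-centering.  Edges of the graph are the
population pairs whose *partial* correlation — the correlation left after
conditioning on every other population — is significantly different from
zero by the edge-exclusion deviance EED = -N ln(1 - rho^2), compared to a
chi-square with one degree of freedom.  Conditional genetic distance
between two populations is the shortest path through the retained edges,
each edge weighted by the centroid distance sqrt(C_ii + C_jj - 2 C_ij).

Congruence of two Population Graphs over the same populations is a
one-tailed Mantel test between their cGD matrices: topologies that share
more structure than expected under random relabeling are congruent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import networkx as nx
import numpy as np
from scipy import stats

from .io_formats import DistanceMatrix, GenotypeMatrix

__all__ = [
    "PopulationGraph",
    "encode_individuals",
    "encode_population_means",
    "among_population_covariance",
    "noise_corrected_covariance",
    "estimate_population_graph",
    "conditional_genetic_distance",
    "mantel",
    "test_congruence",
    "consensus_graph",
    "graph_summary",
]


@dataclass
class PopulationGraph:
    nodes: list[str]
    sigma2_within: dict[str, float]  # within-population variance per node
    edges: list[tuple[str, str, float]]  # (a, b, length), a < b
    alpha: float
    n_individuals: int

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        norm = []
        for a, b, w in self.edges:
            if a == b:
                raise ValueError(f"self-edge at {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
            if not w > 0:
                raise ValueError(f"non-positive edge length on ({a}, {b})")
            norm.append((min(a, b), max(a, b), float(w)))
        self.edges = sorted(norm)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node, sigma2_within=self.sigma2_within.get(node))
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g

    @property
    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())


# ---------------------------------------------------------------------------
# encoding


def encode_individuals(gm: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Encode each individual as a concatenated allele-dosage vector.

    One coordinate per (locus, allele) with value count/2 in {0, 0.5, 1}.
    Missing calls are imputed with the population mean dosage so that every
    individual has a complete vector.  Returns the (individuals x coords)
    matrix and coordinate names "locus:allele".
    """
    coords: list[tuple[int, str]] = []
    names: list[str] = []
    for j, locus in enumerate(gm.locus_ids):
        for allele in sorted(gm.alleles_at(j)):
            coords.append((j, allele))
            names.append(f"{locus}:{allele}")
    X = np.full((gm.n_individuals, len(coords)), np.nan)
    for c, (j, allele) in enumerate(coords):
        for i in range(gm.n_individuals):
            call = gm.calls[i, j]
            if call is None:
                continue
            X[i, c] = ((call[0] == allele) + (call[1] == allele)) / 2.0
    # impute missing entries with the population mean dosage
    for pop in gm.populations:
        rows = gm.individuals_of(pop)
        block = X[rows, :]
        col_means = np.nanmean(
            np.where(np.isnan(block), np.nan, block), axis=0
        )
        col_means = np.nan_to_num(col_means, nan=0.0)
        nan_mask = np.isnan(block)
        block[nan_mask] = np.broadcast_to(col_means, block.shape)[nan_mask]
        X[rows, :] = block
    return X, names


def encode_population_means(
    gm: GenotypeMatrix,
) -> tuple[np.ndarray, dict[str, float], list[str]]:
    """Population centroid vectors and within-population variances.

    sigma^2_W for a population is the mean squared Euclidean distance of
    its individuals to the population centroid; populations with fewer
    than 2 individuals get NaN with a warning.
    """
    if len(gm.populations) < 3:
        raise ValueError("need at least 3 populations")
    X, _ = encode_individuals(gm)
    pops = gm.populations
    means = np.zeros((len(pops), X.shape[1]))
    s2w: dict[str, float] = {}
    for idx, pop in enumerate(pops):
        rows = gm.individuals_of(pop)
        block = X[rows, :]
        means[idx] = block.mean(axis=0)
        if len(rows) < 2:
            warnings.warn(
                f"population {pop!r} has <2 individuals; sigma2_W undefined",
                stacklevel=2,
            )
            s2w[pop] = float("nan")
        else:
            s2w[pop] = float(((block - means[idx]) ** 2).sum(axis=1).mean())
    return means, s2w, pops


def among_population_covariance(means: np.ndarray) -> np.ndarray:
    """Gower double-centering of squared centroid distances.

    With D2 the matrix of squared Euclidean distances between population
    mean vectors and J the centering projector I - 11'/k, returns
    C = -0.5 * J D2 J — the Gram matrix of the centered centroids.
    """
    k = means.shape[0]
    if k < 3:
        raise ValueError("need at least 3 populations")
    diff = means[:, None, :] - means[None, :, :]
    d2 = (diff**2).sum(axis=2)
    j = np.eye(k) - np.ones((k, k)) / k
    return -0.5 * j @ d2 @ j


def noise_corrected_covariance(
    gm: GenotypeMatrix,
) -> tuple[np.ndarray, dict[str, float], list[str]]:
    """Among-population covariance with sampling noise removed.

    Squared distances between *sample* centroids overestimate the true
    centroid distances by the variance of each mean, E[s2_i/n_i + s2_j/n_j]
    with s2 the (unbiased) total within-population variance.  Subtracting
    that term before Gower centering yields an approximately unbiased
    among-population covariance — important for low-information panels
    where sampling noise is comparable to the structure signal.
    """
    means, s2w, pops = encode_population_means(gm)
    k = len(pops)
    n_i = np.array([len(gm.individuals_of(p)) for p in pops], dtype=float)
    # s2w is the mean squared distance to the centroid (/n); rescale to the
    # unbiased variance of the mean: s2w * n/(n-1) / n = s2w/(n-1)
    noise = np.array(
        [s2w[p] / (n - 1) if n > 1 else 0.0 for p, n in zip(pops, n_i)]
    )
    diff = means[:, None, :] - means[None, :, :]
    d2 = (diff**2).sum(axis=2)
    d2c = d2 - noise[:, None] - noise[None, :]
    np.fill_diagonal(d2c, 0.0)
    j = np.eye(k) - np.ones((k, k)) / k
    return -0.5 * j @ d2c @ j, s2w, pops


def estimate_population_graph(
    gm: GenotypeMatrix, alpha: float = 0.05, noise_corrected: bool = True
) -> PopulationGraph:
    """Estimate the Population Graph via edge-exclusion deviance at ``alpha``.

    The precision matrix is the (pseudo-)inverse of the among-population
    covariance; the rank deficiency introduced by centering makes the
    pseudo-inverse the expected path.  An edge i-j is retained when
    EED = -N ln(1 - rho_ij^2) exceeds the chi-square(1) critical value,
    with N the total number of individuals.  ``noise_corrected`` (default)
    removes within-population sampling noise from the covariance first;
    set False for the plain sample-centroid covariance.
    """
    if len(gm.populations) < 4:
        raise ValueError("need at least 4 populations")
    if noise_corrected:
        C, s2w, pops = noise_corrected_covariance(gm)
    else:
        means, s2w, pops = encode_population_means(gm)
        C = among_population_covariance(means)
    k = len(pops)
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > 1e12:
        omega = np.linalg.pinv(C, rcond=1e-12)
    else:
        omega = np.linalg.inv(C)
    d = np.sqrt(np.abs(np.diag(omega)))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    if not np.isfinite(rho).all():
        raise ValueError("non-finite partial correlation")
    rho = np.clip(rho, -0.9999999999, 0.9999999999)
    n_total = gm.n_individuals
    crit = stats.chi2.ppf(1 - alpha, df=1)
    edges: list[tuple[str, str, float]] = []
    for i in range(k):
        for j in range(i + 1, k):
            eed = -n_total * math.log(1 - rho[i, j] ** 2)
            if eed > crit:
                length = math.sqrt(max(C[i, i] + C[j, j] - 2 * C[i, j], 0.0))
                if length > 0:
                    edges.append((pops[i], pops[j], length))
    if not edges:
        raise ValueError("empty graph: no significant partial correlations")
    return PopulationGraph(pops, s2w, edges, alpha, n_total)


# ---------------------------------------------------------------------------
# conditional genetic distance and congruence


def conditional_genetic_distance(g: PopulationGraph) -> DistanceMatrix:
    """All-pairs shortest-path distance over the graph's edge lengths.

    Pairs in different components are NaN; check ``is_connected`` on the
    result before using it in Mantel/MRM machinery.
    """
    if not g.edges:
        raise ValueError("graph has no edges")
    nxg = g.to_networkx()
    k = len(g.nodes)
    out = np.full((k, k), np.nan)
    np.fill_diagonal(out, 0.0)
    index = {n: i for i, n in enumerate(g.nodes)}
    for src, lengths in nx.all_pairs_dijkstra_path_length(nxg, weight="weight"):
        i = index[src]
        for dst, dist in lengths.items():
            out[i, index[dst]] = dist
    return DistanceMatrix(list(g.nodes), out, name="cGD")


def mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    n_perm: int = 9_999,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel correlation between two labeled distance matrices.

    The statistic is the Pearson correlation of the off-diagonal entries;
    significance comes from jointly permuting rows and columns of the
    second matrix.  ``alternative`` is "greater" (default, congruence
    semantics), "less", or "two-sided".
    """
    if dm_a.labels != dm_b.labels:
        dm_b = dm_b.reorder(dm_a.labels)
    a = dm_a.values
    b = dm_b.values
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("distance matrix contains undefined (disconnected) pairs")
    k = len(dm_a.labels)
    iu = np.triu_indices(k, 1)
    va = a[iu]
    vb = b[iu]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance in distances; Mantel undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    if n_perm <= 0:
        return r_obs, float("nan")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        vp = b[np.ix_(perm, perm)][iu]
        r_perm = float(np.corrcoef(va, vp)[0, 1])
        if alternative == "greater":
            hit = r_perm >= r_obs - 1e-12
        elif alternative == "less":
            hit = r_perm <= r_obs + 1e-12
        else:
            hit = abs(r_perm) >= abs(r_obs) - 1e-12
        count += hit
    return r_obs, (1 + count) / (n_perm + 1)


def test_congruence(
    g_a: PopulationGraph,
    g_b: PopulationGraph,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel congruence of two Population Graphs over identical nodes.

    Both graphs must be connected: disjunct components produce undefined
    cGD values and are rejected rather than silently dropped.
    """
    if set(g_a.nodes) != set(g_b.nodes):
        raise ValueError("node sets differ between graphs")
    for name, g in (("first", g_a), ("second", g_b)):
        if not g.is_connected:
            raise ValueError(f"{name} graph contains disjunct groups")
    cgd_a = conditional_genetic_distance(g_a)
    cgd_b = conditional_genetic_distance(g_b).reorder(cgd_a.labels)
    return mantel(cgd_a, cgd_b, n_perm=n_perm, seed=seed, alternative="greater")


def consensus_graph(g_a: PopulationGraph, g_b: PopulationGraph) -> PopulationGraph:
    """Edge intersection of two graphs; lengths are means of the inputs."""
    if set(g_a.nodes) != set(g_b.nodes):
        raise ValueError("node sets differ between graphs")
    wb = {(a, b): w for a, b, w in g_b.edges}
    edges = [
        (a, b, (w + wb[(a, b)]) / 2.0) for a, b, w in g_a.edges if (a, b) in wb
    ]
    if not edges:
        warnings.warn("consensus graph has no edges", stacklevel=2)
    s2w = {
        n: (g_a.sigma2_within.get(n, np.nan) + g_b.sigma2_within.get(n, np.nan)) / 2
        for n in g_a.nodes
    }
    return PopulationGraph(
        list(g_a.nodes), s2w, edges, alpha=max(g_a.alpha, g_b.alpha),
        n_individuals=g_a.n_individuals,
    )


def graph_summary(g: PopulationGraph) -> dict[str, float]:
    """Topology attributes: counts, density, degree, diameter, components."""
    nxg = g.to_networkx()
    k = nxg.number_of_nodes()
    e = nxg.number_of_edges()
    summary = {
        "n_nodes": k,
        "n_edges": e,
        "density": nx.density(nxg),
        "mean_degree": 2 * e / k if k else 0.0,
        "mean_edge_length": (
            float(np.mean([w for _, _, w in g.edges])) if g.edges else float("nan")
        ),
        "n_components": nx.number_connected_components(nxg),
    }
    if g.edges:
        cgd = conditional_genetic_distance(g).values
        finite = cgd[np.isfinite(cgd)]
        summary["diameter"] = float(finite.max())
    else:
        summary["diameter"] = float("nan")
    return summary
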
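"""Population Graph estimation, cGD, Mantel congruence, consensus, summary."""

import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from pinegraph.io_formats import DistanceMatrix
from pinegraph.popgraph import (
    PopulationGraph,
    among_population_covariance,
    conditional_genetic_distance,
    consensus_graph,
    encode_individuals,
    encode_population_means,
    estimate_population_graph,
    graph_summary,
    mantel,
    test_congruence as congruence,
)

from conftest import build_genotype_matrix


def test_dosage_encoding_rule():
    gm = build_genotype_matrix(
        [("p1", "i1", ["A/a"]), ("p1", "i2", ["A/A"]), ("p1", "i3", ["a/a"]),
         ("p2", "i4", ["A/a"]), ("p3", "i5", ["A/A"])],
        ["L1"],
    )
    X, names = encode_individuals(gm)
    assert names == ["L1:A", "L1:a"]
    np.testing.assert_allclose(X[0], [0.5, 0.5])
    np.testing.assert_allclose(X[1], [1.0, 0.0])
    np.testing.assert_allclose(X[2], [0.0, 1.0])


def test_population_means_and_sigma2w():
    gm = build_genotype_matrix(
        [("p1", "i1", ["A/A"]), ("p1", "i2", ["A/A"]),
         ("p2", "i3", ["A/a"]), ("p2", "i4", ["a/a"]),
         ("p3", "i5", ["A/A"]), ("p3", "i6", ["A/a"])],
        ["L1"],
    )
    means, s2w, pops = encode_population_means(gm)
    assert pops == ["p1", "p2", "p3"]
    np.testing.assert_allclose(means[0], [1.0, 0.0])
    np.testing.assert_allclose(means[1], [0.25, 0.75])
    assert s2w["p1"] == pytest.approx(0.0)
    # p2: vectors (0.5,0.5) and (0,1); centroid (0.25,0.75); d2 = 0.125 each
    assert s2w["p2"] == pytest.approx(0.125)


def test_gower_centering_matches_direct_covariance(rng):
    means = rng.normal(size=(5, 4))
    C = among_population_covariance(means)
    centered = means - means.mean(axis=0)
    np.testing.assert_allclose(C, centered @ centered.T, atol=1e-10)
    # identical centroids and collinear layouts
    np.testing.assert_allclose(
        among_population_covariance(np.ones((4, 3))), 0.0, atol=1e-12
    )
    line = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
    assert np.linalg.matrix_rank(among_population_covariance(line), tol=1e-9) == 1


def test_cgd_shortest_paths_and_shortcut():
    chain = PopulationGraph(
        ["A", "B", "C"], {}, [("A", "B", 1.0), ("B", "C", 2.0)], 0.05, 10
    )
    cgd = conditional_genetic_distance(chain)
    assert cgd.values[0, 2] == pytest.approx(3.0)
    triangle = PopulationGraph(
        ["A", "B", "C"], {},
        [("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 5.0)], 0.05, 10,
    )
    cgd2 = conditional_genetic_distance(triangle)
    assert cgd2.values[0, 2] == pytest.approx(2.0)


def test_cgd_matches_floyd_warshall(rng):
    nodes = [f"n{i}" for i in range(8)]
    edges = []
    w = np.full((8, 8), np.inf)
    np.fill_diagonal(w, 0.0)
    for i in range(8):
        for j in range(i + 1, 8):
            if rng.random() < 0.45:
                length = float(rng.random() + 0.1)
                edges.append((nodes[i], nodes[j], length))
                w[i, j] = w[j, i] = length
    g = PopulationGraph(nodes, {}, edges, 0.05, 10)
    cgd = conditional_genetic_distance(g)
    ref = floyd_warshall(np.where(np.isinf(w), 0, w), directed=False)
    ref[np.isinf(ref)] = np.nan
    np.testing.assert_allclose(cgd.values, ref, atol=1e-12, equal_nan=True)
    # triangle inequality on the finite part
    v = cgd.values
    finite = ~np.isnan(v)
    for i in range(8):
        for j in range(8):
            for k in range(8):
                if finite[i, j] and finite[i, k] and finite[k, j]:
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-9


def test_estimated_graph_is_chainlike_on_stepping_stone(sim_toy):
    g = estimate_population_graph(sim_toy["ssr"])
    assert set(g.nodes) == set(sim_toy["ssr"].populations)
    assert all(w > 0 for _, _, w in g.edges)
    assert g.is_connected


def test_edge_test_calibration_under_independence(rng):
    """Behaviour of the edge-exclusion test on exchangeable (unstructured)
    populations.

    Centering the among-population covariance leaves a structural offset:
    the pseudo-inverse partial correlations concentrate at 1/(k-1) rather
    than 0, so the chi-square edge test is anticonservative at nominal
    alpha.  This test pins down that known behaviour: the mean null
    partial correlation matches the centering constant, and a much
    stricter alpha drives the false-edge rate well below 5%.
    """
    from pinegraph.popgraph import (
        among_population_covariance,
        encode_population_means,
    )

    k = 6
    rhos = []
    n_edges_strict = 0
    n_pairs = 0
    for rep in range(30):
        rows = []
        for p in range(k):
            for i in range(12):
                genos = [
                    "/".join(rng.choice(["A", "C"], size=2)) for _ in range(30)
                ]
                rows.append((f"p{p}", f"p{p}i{i}", genos))
        gm = build_genotype_matrix(rows, [f"L{j}" for j in range(30)])
        means, _, _ = encode_population_means(gm)
        C = among_population_covariance(means)
        omega = np.linalg.pinv(C, rcond=1e-12)
        d = np.sqrt(np.abs(np.diag(omega)))
        rho = -omega / np.outer(d, d)
        iu = np.triu_indices(k, 1)
        rhos.extend(rho[iu])
        try:
            g = estimate_population_graph(gm, alpha=1e-6, noise_corrected=False)
            n_edges_strict += len(g.edges)
        except ValueError:
            pass  # empty graph: zero false edges
        n_pairs += k * (k - 1) // 2
    assert np.mean(rhos) == pytest.approx(1 / (k - 1), abs=0.02)
    assert n_edges_strict / n_pairs < 0.05


def test_edge_monotonicity_under_duplication(sim_toy):
    from dataclasses import replace

    gm = sim_toy["snp"]
    g1 = estimate_population_graph(gm)
    individuals, pops = [], {}
    calls = np.empty((2 * gm.n_individuals, gm.n_loci), dtype=object)
    for i, ind in enumerate(gm.individual_ids):
        for c in (0, 1):
            name = f"{ind}_d{c}"
            individuals.append(name)
            pops[name] = gm.population_of_individual[ind]
            calls[2 * i + c] = gm.calls[i]
    gm2 = replace(
        gm, individual_ids=individuals, population_of_individual=pops, calls=calls
    )
    g2 = estimate_population_graph(gm2)
    # doubling N doubles every EED, so the edge set can only grow
    assert set((a, b) for a, b, _ in g1.edges) <= set(
        (a, b) for a, b, _ in g2.edges
    )


def test_mantel_matches_skbio(rng):
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import mantel as sk_mantel

    k = 12
    a = rng.random((k, k)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
    b = rng.random((k, k)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
    labels = [f"n{i}" for i in range(k)]
    dma, dmb = DistanceMatrix(labels, a), DistanceMatrix(labels, b)
    r, p = mantel(dma, dmb, n_perm=999, seed=0, alternative="greater")
    sk_r, sk_p, _ = sk_mantel(
        skbio.DistanceMatrix(a, labels),
        skbio.DistanceMatrix(b, labels),
        method="pearson",
        permutations=999,
        alternative="greater",
    )
    assert r == pytest.approx(sk_r, abs=1e-12)
    assert p == pytest.approx(sk_p, abs=0.05)


def test_mantel_self_and_scale_invariance(rng):
    nodes = [f"n{i}" for i in range(8)]
    edges = [
        (nodes[i], nodes[i + 1], float(rng.random() + 0.2)) for i in range(7)
    ]
    cgd = conditional_genetic_distance(PopulationGraph(nodes, {}, edges, 0.05, 10))
    r, p = mantel(cgd, cgd, n_perm=499, seed=1)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(1 / 500, abs=1e-12)
    doubled = DistanceMatrix(cgd.labels, 2 * cgd.values)
    r2, _ = mantel(cgd, doubled, n_perm=0)
    assert r2 == pytest.approx(1.0)


def test_congruence_rejects_disconnected():
    g_ok = PopulationGraph(["A", "B", "C"], {}, [("A", "B", 1.0), ("B", "C", 1.0)],
                           0.05, 10)
    g_dis = PopulationGraph(["A", "B", "C"], {}, [("A", "B", 1.0)], 0.05, 10)
    with pytest.raises(ValueError, match="disjunct"):
        congruence(g_ok, g_dis, n_perm=9)
    with pytest.raises(ValueError, match="node sets"):
        congruence(g_ok, PopulationGraph(["A", "B"], {}, [("A", "B", 1.0)], 0.05, 10))


def test_consensus_graph_intersection():
    g1 = PopulationGraph(["A", "B", "C"], {"A": 1.0, "B": 1.0, "C": 1.0},
                         [("A", "B", 1.0), ("B", "C", 2.0)], 0.05, 10)
    g2 = PopulationGraph(["A", "B", "C"], {"A": 1.0, "B": 1.0, "C": 1.0},
                         [("A", "B", 3.0), ("A", "C", 1.0)], 0.05, 10)
    cons = consensus_graph(g1, g2)
    assert cons.edges == [("A", "B", 2.0)]
    same = consensus_graph(g1, g1)
    assert same.edges == g1.edges
    with pytest.warns(UserWarning, match="no edges"):
        g3 = PopulationGraph(["A", "B", "C"], {}, [("A", "C", 1.0)], 0.05, 10)
        empty = consensus_graph(g1, g3)
    assert empty.edges == []


def test_graph_summary_counts():
    chain = PopulationGraph(
        ["A", "B", "C", "D"], {},
        [("A", "B", 1.0), ("B", "C", 1.0), ("C", "D", 1.0)], 0.05, 10,
    )
    s = graph_summary(chain)
    assert s["n_edges"] == 3 and s["density"] == pytest.approx(0.5)
    assert s["diameter"] == pytest.approx(3.0)
    full = PopulationGraph(
        ["A", "B", "C", "D", "E"], {},
        [(a, b, 1.0) for i, a in enumerate("ABCDE") for b in "ABCDE"[i + 1:]],
        0.05, 10,
    )
    s2 = graph_summary(full)
    assert s2["density"] == pytest.approx(1.0)
    assert s2["mean_degree"] == pytest.approx(4.0)
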
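"""RDA/pRDA, stepwise selection, variance partitioning, and MRM."""

import numpy as np
import pandas as pd
import pytest

from pinegraph.assoc_multi import (
    adjusted_r2,
    conditional_adjusted_r2,
    mrm,
    mrm_conditional,
    permutation_anova,
    prda,
    rda,
    stepwise_select,
    variance_partition,
)
from pinegraph.climate_prep import TrendSurface
from pinegraph.io_formats import DistanceMatrix


def random_distance(rng, k, labels=None):
    pts = rng.normal(size=(k, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    return DistanceMatrix(labels or [f"n{i}" for i in range(k)], d)


def test_rda_extremes(rng):
    n = 20
    X = rng.normal(size=(n, 2))
    B = rng.normal(size=(2, 5))
    exact = rda(X @ B, X)
    assert exact.r2 == pytest.approx(1.0)
    # Y orthogonal to X by construction: residualize Y on X
    Y = rng.normal(size=(n, 4))
    Xc = X - X.mean(axis=0)
    Yr = Y - Xc @ np.linalg.lstsq(Xc, Y - Y.mean(axis=0), rcond=None)[0]
    assert rda(Yr, X).r2 == pytest.approx(0.0, abs=1e-10)


def test_rda_inertia_longhand(rng):
    Y = rng.normal(size=(10, 6))
    X = rng.normal(size=(10, 2))
    res = rda(Y, X)
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    H = Xc @ np.linalg.inv(Xc.T @ Xc) @ Xc.T
    Yhat = H @ Yc
    assert res.constrained_inertia == pytest.approx(
        np.trace(Yhat.T @ Yhat) / 9, rel=1e-10
    )
    assert res.eigenvalues.sum() == pytest.approx(res.constrained_inertia, rel=1e-10)


def test_rda_invariant_to_reparameterization(rng):
    Y = rng.normal(size=(15, 4))
    X = rng.normal(size=(15, 3))
    A = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # invertible
    assert rda(Y, X).r2 == pytest.approx(rda(Y, X @ A).r2, rel=1e-10)


def test_rda_matches_vegan(tmp_path, rng):
    """Cross-check R2 and adjusted R2 against vegan's rda()."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    Y = rng.normal(size=(12, 5))
    X = rng.normal(size=(12, 2))
    np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
    np.savetxt(tmp_path / "X.csv", X, delimiter=",")
    script = tmp_path / "rda.R"
    script.write_text(
        'suppressMessages(library(vegan))\n'
        f'Y <- as.matrix(read.csv("{tmp_path}/Y.csv", header=FALSE))\n'
        f'X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))\n'
        "fit <- rda(Y ~ X)\n"
        "r2 <- RsquareAdj(fit)\n"
        'cat(sprintf("%.12f %.12f", r2$r.squared, r2$adj.r.squared))\n'
    )
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
    )
    assert out.returncode == 0, out.stderr
    r2_ref, adj_ref = map(float, out.stdout.split())
    res = rda(Y, X)
    assert res.r2 == pytest.approx(r2_ref, abs=1e-8)
    assert adjusted_r2(res) == pytest.approx(adj_ref, abs=1e-8)


def test_prda_reductions_and_errors(rng):
    n = 20
    Y = rng.normal(size=(n, 3))
    X = rng.normal(size=(n, 2))
    Z = rng.normal(size=(n, 2))
    with pytest.raises(ValueError, match="nothing to test"):
        prda(Y, X, X)
    # planted: Y = Z-signal + X-signal; pRDA recovers only the X share
    bx = rng.normal(size=(2, 3))
    bz = rng.normal(size=(2, 3))
    Yp = X @ bx + Z @ bz
    res = prda(Yp, X, Z)
    assert res.r2 == pytest.approx(1.0, abs=1e-8)
    res0 = prda(Z @ bz + 0.01 * rng.normal(size=(n, 3)), X, Z)
    assert res0.r2 < 0.35


def test_adjusted_r2_closed_forms():
    res = rda(np.eye(4), np.eye(4)[:, :1])  # placeholder fit, overwrite fields
    res.r2, res.n, res.m, res.q = 1.0, 10, 3, 0
    assert adjusted_r2(res) == pytest.approx(1.0)
    res.r2, res.n, res.m = 0.0, 29, 9
    assert adjusted_r2(res) == pytest.approx(-9 / 19)


def test_conditional_adjusted_r2_nested_identity(rng):
    Y = rng.normal(size=(25, 4))
    X = rng.normal(size=(25, 3))
    Z = rng.normal(size=(25, 2))
    XZ = np.column_stack([X, Z])
    lhs = adjusted_r2(rda(Y, XZ))
    rhs = adjusted_r2(rda(Y, Z)) + conditional_adjusted_r2(Y, X, Z)
    assert lhs == pytest.approx(rhs, abs=1e-12)


def test_permutation_anova_signal_and_null(rng):
    n = 18
    X = rng.normal(size=(n, 2))
    Y = X @ rng.normal(size=(2, 3))
    f, p = permutation_anova(rda(Y, X), n_perm=199, seed=0)
    assert p == pytest.approx(1 / 200)
    ps = []
    for _ in range(60):
        Yn = rng.normal(size=(n, 3))
        _, p0 = permutation_anova(
            rda(Yn, X), n_perm=99, seed=int(rng.integers(2**31))
        )
        ps.append(p0)
    from scipy import stats

    assert stats.kstest(ps, "uniform").pvalue > 0.001
    axis = permutation_anova(rda(Y, X), n_perm=99, by="axis", seed=1)
    assert (axis["p"] >= 1 / 100).all()


def _surface(rng, n=30, terms=("x", "y", "x^3")):
    pos = rng.normal(size=(n, 1))
    cols = {"x": pos[:, 0], "y": rng.normal(size=n)}
    cols["x^3"] = cols["x"] ** 3
    df = pd.DataFrame({t: cols[t] for t in terms},
                      index=[f"p{i}" for i in range(n)])
    return TrendSurface(df - df.mean())


def test_stepwise_selects_planted_terms(rng):
    surf = _surface(rng)
    Y = np.column_stack([
        2 * surf.terms["x"] + 1.5 * surf.terms["x^3"] + 0.1 * rng.normal(size=30)
        for _ in range(3)
    ])
    selected, trail = stepwise_select(Y, surf, seed=11)
    assert set(selected) == {"x", "x^3"}
    assert trail
    # single candidate equal to the response is selected
    surf1 = TrendSurface(surf.terms[["y"]])
    sel1, _ = stepwise_select(surf.terms[["y"]].to_numpy(), surf1, seed=3)
    assert sel1 == ["y"]


def test_stepwise_null_rarely_selects(rng):
    surf = _surface(rng, terms=("x", "y"))
    n_sel = 0
    for rep in range(10):
        Y = rng.normal(size=(30, 3))
        sel, _ = stepwise_select(Y, surf, seed=int(rng.integers(2**31)))
        n_sel += len(sel)
    assert n_sel <= 3  # ~5% per-term false entry


def test_variance_partition_reconstruction(rng):
    n = 24
    Xc = rng.normal(size=(n, 3))
    Xg = rng.normal(size=(n, 2))
    Y = Xc @ rng.normal(size=(3, 5)) + Xg @ rng.normal(size=(2, 5)) \
        + rng.normal(size=(n, 5))
    part = variance_partition(Y, Xc, Xg)
    total = (
        part.climate_independent + part.geography_independent + part.confounded
    )
    assert total == pytest.approx(1.0, abs=1e-9)
    # identical predictor sets are fully confounded
    same = variance_partition(Y, Xc, Xc.copy())
    assert same.confounded == pytest.approx(1.0, abs=1e-9)
    # orthogonalized blocks with disjoint effects barely overlap
    Xg_orth = Xg - Xc @ np.linalg.lstsq(Xc, Xg, rcond=None)[0]
    Y2 = Xc @ rng.normal(size=(3, 5)) + Xg_orth @ rng.normal(size=(2, 5))
    part2 = variance_partition(Y2, Xc, Xg_orth)
    assert abs(part2.confounded) < 0.05


def test_mrm_exact_fit_and_single_predictor_is_mantel(rng):
    from pinegraph.popgraph import mantel

    k = 10
    pred = random_distance(rng, k)
    resp = DistanceMatrix(pred.labels, 3 * pred.values)
    res = mrm(resp, pred, n_perm=99, seed=0)
    assert res.coefficients[list(res.coefficients)[0]] == pytest.approx(3.0)
    assert res.r2 == pytest.approx(1.0)
    resp2 = random_distance(rng, k, labels=pred.labels)
    res2 = mrm(resp2, pred, n_perm=0)
    r_mantel, _ = mantel(resp2, pred, n_perm=0)
    assert res2.r2 == pytest.approx(r_mantel**2, abs=1e-12)


def test_mrm_permutation_p_bounds(rng):
    k = 9
    ps = []
    for _ in range(25):
        a = random_distance(rng, k)
        b = random_distance(rng, k, labels=a.labels)
        res = mrm(a, b, n_perm=99, seed=int(rng.integers(2**31)))
        ps.append(res.p)
        assert 1 / 100 <= res.p <= 1.0
    assert np.mean(ps) > 0.2  # not systematically significant under the null


def test_mrm_rejects_undefined_response(rng):
    k = 5
    a = random_distance(rng, k)
    vals = a.values.copy()
    vals[0, 1] = vals[1, 0] = np.nan
    broken = DistanceMatrix(a.labels, vals)
    with pytest.raises(ValueError, match="undefined"):
        mrm(broken, a, n_perm=0)


def test_mrm_conditional_reductions(rng):
    k = 12
    pred = random_distance(rng, k)
    cond = random_distance(rng, k, labels=pred.labels)
    resp = DistanceMatrix(pred.labels, pred.values + 0.01 * cond.values)
    # conditioning on the predictor itself leaves nothing
    res_self = mrm_conditional(resp, pred, pred, n_perm=0)
    assert res_self.r2 == pytest.approx(0.0, abs=1e-6)
    # conditioning on an unrelated matrix barely changes the fit
    res_un = mrm_conditional(resp, cond, pred, n_perm=0)
    res_raw = mrm(resp, pred, n_perm=0)
    assert res_un.r2 == pytest.approx(res_raw.r2, abs=0.1)
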
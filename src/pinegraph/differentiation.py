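"""Population differentiation and linkage disequilibrium.

F_ST follows Weir & Cockerham (1984): per-allele variance components a
(among populations), b (among individuals within populations) and c
(within individuals) are summed over alleles and loci, and the multilocus
estimate is the ratio of summed components theta = sum(a)/sum(a+b+c) —
never a mean of per-locus ratios.  Hedrick's (2005) G'_ST rescales Nei's
G_ST by its maximum attainable value given the within-population
heterozygosity, making multi-allelic and biallelic panels comparable.
Hierarchical F-statistics add a grouping level (e.g. climate groups) above
populations via nested ANOVA on allele indicators.  Pairwise linkage
disequilibrium (r^2, |D'|) is estimated from unphased diploid genotypes by
an EM fit of two-locus haplotype frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix
from .diversity import allele_frequencies

__all__ = [
    "FstResult",
    "LDRecord",
    "wc_fst",
    "nei_gst",
    "gst_prime",
    "hierarchical_fstats",
    "ld_pairwise",
]


@dataclass
class FstResult:
    per_locus: pd.DataFrame  # locus-indexed statistics
    multilocus: float
    ci: tuple[float, float] | None
    statistic: str = "F_ST"
    # hierarchical components, populated by hierarchical_fstats
    sigma2_group: float | None = None
    sigma2_pop: float | None = None
    sigma2_within: float | None = None
    group_fraction: float | None = None
    notes: list[str] = field(default_factory=list)


@dataclass
class LDRecord:
    locus_a: str
    locus_b: str
    r2: float
    d_prime: float
    klass: str  # "intragenic" or "intergenic"


# ---------------------------------------------------------------------------
# Weir-Cockerham theta


def _wc_components_locus(gm: GenotypeMatrix, j: int) -> tuple[float, float, float]:
    """Summed (a, b, c) components over alleles at locus ``j``."""
    pops = gm.populations
    n_i: list[float] = []  # individuals sampled per population
    p_ia: list[dict[str, float]] = []  # allele frequency per population
    h_ia: list[dict[str, float]] = []  # frequency of heterozygotes carrying allele
    alleles: set[str] = set()
    for pop in pops:
        counts: dict[str, int] = {}
        hets: dict[str, int] = {}
        n = 0
        for i in gm.individuals_of(pop):
            call = gm.calls[i, j]
            if call is None:
                continue
            n += 1
            a, b = call
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
            if a != b:
                hets[a] = hets.get(a, 0) + 1
                hets[b] = hets.get(b, 0) + 1
        if n == 0:
            continue
        n_i.append(n)
        p_ia.append({al: c / (2 * n) for al, c in counts.items()})
        h_ia.append({al: c / n for al, c in hets.items()})
        alleles.update(counts)
    r = len(n_i)
    if r < 2 or len(alleles) < 2:
        return 0.0, 0.0, 0.0
    n_arr = np.array(n_i, dtype=float)
    n_bar = n_arr.mean()
    n_c = (r * n_bar - (n_arr**2).sum() / (r * n_bar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p = np.array([d.get(al, 0.0) for d in p_ia])
        h = np.array([d.get(al, 0.0) for d in h_ia])
        p_bar = (n_arr * p).sum() / (r * n_bar)
        s2 = (n_arr * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_arr * h).sum() / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_fst(
    gm: GenotypeMatrix, n_boot: int = 10_000, seed: int | None = None
) -> FstResult:
    """Multilocus Weir-Cockerham theta with a percentile CI over loci."""
    if len(gm.populations) < 2:
        raise ValueError("F_ST needs at least 2 populations")
    comps = np.array([_wc_components_locus(gm, j) for j in range(gm.n_loci)])
    a, b, c = comps[:, 0], comps[:, 1], comps[:, 2]
    denom = a + b + c
    informative = denom != 0
    with np.errstate(divide="ignore", invalid="ignore"):
        per_locus_theta = np.where(informative, a / np.where(denom == 0, 1, denom), np.nan)
    multilocus = float(a.sum() / denom.sum())
    per_locus = pd.DataFrame(
        {"a": a, "b": b, "c": c, "F_ST": per_locus_theta}, index=gm.locus_ids
    )
    ci = _bootstrap_ratio_ci(a, denom, n_boot, seed)
    notes = [] if informative.sum() >= 2 else ["CI unavailable: <2 informative loci"]
    if informative.sum() < 2:
        ci = None
    return FstResult(per_locus, multilocus, ci, statistic="F_ST", notes=notes)


def _bootstrap_ratio_ci(num, denom, n_boot, seed) -> tuple[float, float] | None:
    """Percentile CI of sum(num)/sum(denom) under locus resampling."""
    L = len(num)
    if L < 2 or n_boot <= 0:
        return None
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, L, size=(n_boot, L))
    ns = num[idx].sum(axis=1)
    ds = denom[idx].sum(axis=1)
    ok = ds != 0
    vals = ns[ok] / ds[ok]
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Nei G_ST and Hedrick G'_ST


def _nei_hs_ht_locus(gm: GenotypeMatrix, j: int) -> tuple[float, float] | None:
    """Sample-size-corrected (H_S, H_T) estimators (Nei & Chesser 1983)."""
    pops = gm.populations
    p_rows = []
    n_i = []
    ho_i = []
    alleles: set[str] = set()
    per_pop: list[dict[str, float]] = []
    for pop in pops:
        counts: dict[str, int] = {}
        n = 0
        het = 0
        for i in gm.individuals_of(pop):
            call = gm.calls[i, j]
            if call is None:
                continue
            n += 1
            counts[call[0]] = counts.get(call[0], 0) + 1
            counts[call[1]] = counts.get(call[1], 0) + 1
            if call[0] != call[1]:
                het += 1
        if n == 0:
            continue
        n_i.append(n)
        ho_i.append(het / n)
        per_pop.append({al: c / (2 * n) for al, c in counts.items()})
        alleles.update(counts)
    k = len(n_i)
    if k < 2:
        return None
    n_harm = k / np.sum(1.0 / np.asarray(n_i, dtype=float))
    allele_list = sorted(alleles)
    P = np.array([[d.get(al, 0.0) for al in allele_list] for d in per_pop])
    ho = float(np.mean(ho_i))
    hs_plug = 1.0 - float(np.mean((P**2).sum(axis=1)))
    p_bar = P.mean(axis=0)
    ht_plug = 1.0 - float((p_bar**2).sum())
    hs = n_harm / (n_harm - 1) * (hs_plug - ho / (2 * n_harm))
    ht = ht_plug + hs / (n_harm * k) - ho / (2 * n_harm * k)
    return hs, ht


def nei_gst(gm: GenotypeMatrix) -> tuple[float, pd.DataFrame]:
    """Multilocus Nei G_ST from averaged corrected H_S and H_T."""
    rows = []
    for j, locus in enumerate(gm.locus_ids):
        est = _nei_hs_ht_locus(gm, j)
        if est is None:
            continue
        hs, ht = est
        gst = (ht - hs) / ht if ht > 0 else np.nan
        rows.append((locus, hs, ht, gst))
    df = pd.DataFrame(rows, columns=["locus", "H_S", "H_T", "G_ST"]).set_index("locus")
    hs_bar, ht_bar = df["H_S"].mean(), df["H_T"].mean()
    return float((ht_bar - hs_bar) / ht_bar), df


def _gst_prime_from(hs: float, ht: float, k: int) -> float:
    if ht <= 0 or hs >= 1:
        return np.nan
    gst = (ht - hs) / ht
    return gst * (k - 1 + hs) / ((k - 1) * (1 - hs))


def gst_prime(
    gm: GenotypeMatrix, n_boot: int = 10_000, seed: int | None = None
) -> FstResult:
    """Hedrick's standardized G'_ST with a locus-bootstrap CI.

    Multilocus values use H_S and H_T averaged across loci before
    standardization.
    """
    k = len(gm.populations)
    if k < 2:
        raise ValueError("G'_ST needs at least 2 populations")
    _, df = nei_gst(gm)
    if df.empty:
        raise ValueError("no informative loci")
    df = df.copy()
    df["G_ST_prime"] = [
        _gst_prime_from(hs, ht, k) for hs, ht in zip(df["H_S"], df["H_T"])
    ]
    multilocus = _gst_prime_from(float(df["H_S"].mean()), float(df["H_T"].mean()), k)
    hs = df["H_S"].to_numpy()
    ht = df["H_T"].to_numpy()
    L = len(df)
    ci = None
    if L >= 2 and n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, L, size=(n_boot, L))
        vals = np.array(
            [_gst_prime_from(hs[i].mean(), ht[i].mean(), k) for i in idx]
        )
        vals = vals[np.isfinite(vals)]
        lo, hi = np.percentile(vals, [2.5, 97.5])
        ci = (float(lo), float(hi))
    return FstResult(df, multilocus, ci, statistic="G_ST_prime")


# ---------------------------------------------------------------------------
# hierarchical F-statistics


def hierarchical_fstats(
    gm: GenotypeMatrix, grouping: dict[str, str]
) -> FstResult:
    """Three-level variance components: group / population-in-group / within.

    Gene copies carry allele-indicator responses; components come from the
    unbalanced nested ANOVA moment estimators, summed over alleles and
    loci.  Negative component estimates are reported as-is (they are
    effectively zero).  The headline quantity is the group-level fraction
    sigma2_group / (sigma2_group + sigma2_pop).
    """
    pops = gm.populations
    missing = [p for p in pops if p not in grouping]
    if missing:
        raise ValueError(f"grouping lacks populations: {missing}")
    groups = sorted(set(grouping[p] for p in pops))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    s2g_total = s2p_total = s2w_total = 0.0
    per_locus_rows = []
    for j, locus in enumerate(gm.locus_ids):
        # collect gene-copy responses per population
        copies: dict[str, list[str]] = {p: [] for p in pops}
        alleles: set[str] = set()
        for p in pops:
            for i in gm.individuals_of(p):
                call = gm.calls[i, j]
                if call is None:
                    continue
                copies[p].extend(call)
                alleles.update(call)
        if len(alleles) < 2:
            continue
        s2g_l = s2p_l = s2w_l = 0.0
        for al in sorted(alleles):
            comp = _nested_components(copies, grouping, groups, al)
            if comp is None:
                continue
            s2g_l += comp[0]
            s2p_l += comp[1]
            s2w_l += comp[2]
        s2g_total += s2g_l
        s2p_total += s2p_l
        s2w_total += s2w_l
        denom = s2g_l + s2p_l
        per_locus_rows.append(
            (locus, s2g_l, s2p_l, s2w_l, s2g_l / denom if denom > 0 else np.nan)
        )
    per_locus = pd.DataFrame(
        per_locus_rows,
        columns=["locus", "sigma2_group", "sigma2_pop", "sigma2_within", "fraction"],
    ).set_index("locus")
    denom = s2g_total + s2p_total
    fraction = s2g_total / denom if denom > 0 else np.nan
    total = s2g_total + s2p_total + s2w_total
    res = FstResult(
        per_locus,
        multilocus=s2g_total / total if total > 0 else np.nan,
        ci=None,
        statistic="hierarchical",
        sigma2_group=s2g_total,
        sigma2_pop=s2p_total,
        sigma2_within=s2w_total,
        group_fraction=fraction,
        notes=["Negative variance components are effectively zero"],
    )
    return res


def _nested_components(
    copies: dict[str, list[str]],
    grouping: dict[str, str],
    groups: list[str],
    allele: str,
) -> tuple[float, float, float] | None:
    """Moment estimators for one allele indicator in a two-fold nested design."""
    y_gp: dict[str, list[np.ndarray]] = {g: [] for g in groups}
    for pop, cs in copies.items():
        if not cs:
            continue
        y = np.array([1.0 if c == allele else 0.0 for c in cs])
        y_gp[grouping[pop]].append(y)
    y_gp = {g: ys for g, ys in y_gp.items() if ys}
    G = len(y_gp)
    P = sum(len(ys) for ys in y_gp.values())
    N = sum(len(y) for ys in y_gp.values() for y in ys)
    if G < 2 or N <= P:
        return None
    grand = sum(y.sum() for ys in y_gp.values() for y in ys) / N
    ss_g = ss_p = ss_w = 0.0
    sum_np2_over_Ng = 0.0
    sum_np2 = 0.0
    sum_Ng2 = 0.0
    for g, ys in y_gp.items():
        N_g = sum(len(y) for y in ys)
        mean_g = sum(y.sum() for y in ys) / N_g
        ss_g += N_g * (mean_g - grand) ** 2
        sum_Ng2 += N_g**2
        np2 = 0.0
        for y in ys:
            n = len(y)
            m = y.mean()
            ss_p += n * (m - mean_g) ** 2
            ss_w += ((y - m) ** 2).sum()
            np2 += n**2
        sum_np2_over_Ng += np2 / N_g
        sum_np2 += np2
    df_g = G - 1
    df_p = P - G
    df_w = N - P
    ms_w = ss_w / df_w
    s2w = ms_w
    if df_p > 0:
        k1 = (N - sum_np2_over_Ng) / df_p
        ms_p = ss_p / df_p
        s2p = (ms_p - ms_w) / k1 if k1 > 0 else 0.0
    else:
        s2p = 0.0
    k2 = (sum_np2_over_Ng - sum_np2 / N) / df_g
    k3 = (N - sum_Ng2 / N) / df_g
    ms_g = ss_g / df_g
    s2g = (ms_g - ms_w - k2 * s2p) / k3 if k3 > 0 else 0.0
    return s2g, s2p, s2w


# ---------------------------------------------------------------------------
# linkage disequilibrium


def _biallelic_dosage(gm: GenotypeMatrix, j: int) -> tuple[np.ndarray, str] | None:
    """Dosage of the alphabetically-first allele; None if not 2 alleles."""
    alleles = sorted(gm.alleles_at(j))
    if len(alleles) != 2:
        return None
    focal = alleles[0]
    dose = np.full(gm.n_individuals, -1, dtype=int)
    for i in range(gm.n_individuals):
        call = gm.calls[i, j]
        if call is None:
            continue
        dose[i] = (call[0] == focal) + (call[1] == focal)
    return dose, focal


def _em_haplotypes(
    dose_a: np.ndarray, dose_b: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[float, float, float] | None:
    """EM estimate of (pA, pB, D) from unphased two-locus dosages."""
    ok = (dose_a >= 0) & (dose_b >= 0)
    a = dose_a[ok]
    b = dose_b[ok]
    n = len(a)
    if n == 0:
        return None
    pA = a.sum() / (2 * n)
    pB = b.sum() / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return None
    # only double heterozygotes are phase-ambiguous; every other genotype
    # contributes a*b/2 AB haplotypes with certainty
    n_dh = int(((a == 1) & (b == 1)).sum())
    fixed_ab = (float((a * b).sum()) - n_dh) / 2.0
    p_ab = pA * pB  # start at linkage equilibrium
    ll_old = -np.inf
    for _ in range(max_iter):
        p_Ab = pA - p_ab
        p_aB = pB - p_ab
        p_ab_c = 1 - pA - pB + p_ab
        cis = p_ab * p_ab_c
        trans = p_Ab * p_aB
        frac = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new_ab = (fixed_ab + n_dh * frac) / (2 * n)
        # log-likelihood of double hets (the only term that moves)
        ll = n_dh * np.log(cis + trans) if (cis + trans) > 0 else -np.inf
        if abs(ll - ll_old) < tol:
            p_ab = new_ab
            break
        ll_old = ll
        p_ab = new_ab
    D = p_ab - pA * pB
    return pA, pB, D


def ld_pairwise(gm: GenotypeMatrix) -> list[LDRecord]:
    """r^2 and |D'| for every polymorphic biallelic locus pair, pooled.

    Pairs are classed intragenic when both loci map to the same gene/contig
    label, otherwise intergenic; unlabeled loci yield intergenic pairs.
    """
    if gm.n_loci < 2:
        raise ValueError("need at least 2 loci")
    doses = [_biallelic_dosage(gm, j) for j in range(gm.n_loci)]
    records: list[LDRecord] = []
    gene = gm.gene_of_locus or {}
    for j1 in range(gm.n_loci):
        if doses[j1] is None:
            continue
        for j2 in range(j1 + 1, gm.n_loci):
            if doses[j2] is None:
                continue
            est = _em_haplotypes(doses[j1][0], doses[j2][0])
            if est is None:
                continue
            pA, pB, D = est
            denom = pA * (1 - pA) * pB * (1 - pB)
            r2 = D**2 / denom
            if D >= 0:
                dmax = min(pA * (1 - pB), (1 - pA) * pB)
            else:
                dmax = min(pA * pB, (1 - pA) * (1 - pB))
            d_prime = abs(D) / dmax if dmax > 0 else np.nan
            la, lb = gm.locus_ids[j1], gm.locus_ids[j2]
            same_gene = (
                la in gene and lb in gene and gene[la] == gene[lb]
            )
            records.append(
                LDRecord(la, lb, float(r2), float(d_prime),
                         "intragenic" if same_gene else "intergenic")
            )
    return records
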
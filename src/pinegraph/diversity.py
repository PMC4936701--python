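"""Per-population genetic diversity and its geographic correlates.

For each population x locus cell the module computes the effective number
of alleles A_E = 1/sum(p^2), observed heterozygosity H_O, expected
heterozygosity H_E = 1 - sum(p^2) (optionally Nei's 1978 small-sample
correction), and the inbreeding coefficient F_IS = 1 - H_O/H_E.
Multilocus population values are unweighted means across loci; by default
the multilocus F_IS is the ratio of the mean heterozygosities (1 - mean
H_O / mean H_E) rather than a mean of per-locus ratios.  Uncertainty on
range-wide averages comes from bootstrap resampling of populations, and
geographic trends are tested by permutation of population identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

__all__ = [
    "AlleleFrequencyTable",
    "DiversityTable",
    "allele_frequencies",
    "diversity_stats",
    "bootstrap_population_means",
    "permutation_pearson",
]

STATS = ("A_E", "H_O", "H_E", "F_IS")


@dataclass
class AlleleFrequencyTable:
    """Per-population, per-locus allele frequencies and gene-copy counts."""

    populations: list[str]
    loci: list[str]
    freqs: dict[tuple[str, str], dict[str, float]]  # (pop, locus) -> allele -> p
    n_genes: pd.DataFrame  # population x locus, sampled gene copies

    def frequency(self, pop: str, locus: str, allele: str) -> float:
        return self.freqs[(pop, locus)].get(allele, 0.0)

    def alleles(self, locus: str) -> list[str]:
        out: set[str] = set()
        for pop in self.populations:
            out.update(self.freqs[(pop, locus)])
        return sorted(out)


@dataclass
class DiversityTable:
    per_locus: pd.DataFrame  # columns population, locus, A_E, H_O, H_E, F_IS
    per_population: pd.DataFrame  # population x statistic (multilocus means)


def allele_frequencies(gm: GenotypeMatrix) -> AlleleFrequencyTable:
    pops = gm.populations
    freqs: dict[tuple[str, str], dict[str, float]] = {}
    n_genes = pd.DataFrame(0, index=pops, columns=gm.locus_ids, dtype=int)
    for pop in pops:
        rows = gm.individuals_of(pop)
        for j, locus in enumerate(gm.locus_ids):
            counts: dict[str, int] = {}
            n = 0
            for i in rows:
                call = gm.calls[i, j]
                if call is None:
                    continue
                n += 2
                for a in call:
                    counts[a] = counts.get(a, 0) + 1
            n_genes.loc[pop, locus] = n
            freqs[(pop, locus)] = (
                {a: c / n for a, c in counts.items()} if n else {}
            )
    return AlleleFrequencyTable(pops, list(gm.locus_ids), freqs, n_genes)


def diversity_stats(
    gm: GenotypeMatrix, unbiased: bool = False
) -> DiversityTable:
    """Compute A_E, H_O, H_E and F_IS per population and locus.

    ``unbiased=True`` applies Nei's (1978) correction
    ``H_E * 2n/(2n-1)`` with 2n the sampled gene copies.
    """
    aft = allele_frequencies(gm)
    records = []
    for pop in aft.populations:
        rows = gm.individuals_of(pop)
        for j, locus in enumerate(gm.locus_ids):
            p = np.array(list(aft.freqs[(pop, locus)].values()))
            n2 = aft.n_genes.loc[pop, locus]
            if n2 == 0:
                records.append((pop, locus, np.nan, np.nan, np.nan, np.nan))
                continue
            sum_p2 = float((p**2).sum())
            he = 1.0 - sum_p2
            if unbiased and n2 > 1:
                he = he * n2 / (n2 - 1)
            ae = 1.0 / sum_p2
            het = 0
            n_called = 0
            for i in rows:
                call = gm.calls[i, j]
                if call is None:
                    continue
                n_called += 1
                if call[0] != call[1]:
                    het += 1
            ho = het / n_called
            fis = 1.0 - ho / he if he > 0 else np.nan
            records.append((pop, locus, ae, ho, he, fis))
    per_locus = pd.DataFrame(
        records, columns=["population", "locus", "A_E", "H_O", "H_E", "F_IS"]
    )
    means = per_locus.groupby("population")[["A_E", "H_O", "H_E"]].mean()
    # ratio-of-means F_IS so that rare alleles at individual loci do not
    # dominate the population value
    means["F_IS"] = 1.0 - means["H_O"] / means["H_E"]
    return DiversityTable(per_locus, means.loc[sorted(means.index)])


def bootstrap_population_means(
    dt: DiversityTable, n: int = 10_000, seed: int | None = None
) -> pd.DataFrame:
    """Percentile 95% CIs for across-population means of each statistic.

    Populations are resampled with replacement ``n`` times; returns a frame
    indexed by statistic with columns mean, lo, hi.
    """
    if n < 100:
        import warnings

        warnings.warn(f"n = {n} bootstrap replicates is very small", stacklevel=2)
    rng = np.random.default_rng(seed)
    values = dt.per_population[list(STATS)].to_numpy()
    k = values.shape[0]
    if k < 2:
        raise ValueError("need at least 2 populations to bootstrap")
    idx = rng.integers(0, k, size=(n, k))
    boot_means = values[idx].mean(axis=1)  # n x statistic
    lo, hi = np.percentile(boot_means, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"mean": values.mean(axis=0), "lo": lo, "hi": hi}, index=list(STATS)
    )


def permutation_pearson(
    x, y, n: int = 9_999, seed: int | None = None
) -> tuple[float, float]:
    """Pearson r with a two-sided permutation p-value.

    p = (1 + #{|r_perm| >= |r_obs|}) / (n + 1), permuting the pairing of
    population identifiers.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    count = 0
    for _ in range(n):
        r_perm = float(xc @ rng.permutation(yc)) / denom
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
    return r_obs, (1 + count) / (n + 1)
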
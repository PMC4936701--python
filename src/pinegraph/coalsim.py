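"""Stepping-stone coalescent simulator and marker-comparison experiments.

The synthetic-data engine mirrors the study conditions used to calibrate
marker-type differences: ten demes on a one-dimensional chain with a
global effective size of N_e = 10,000 diploids split evenly across demes,
adjacent demes exchanging migrants at 2*N_e*m = 2.5 (per-deme scaling);
ten diploid individuals sampled per deme.  Two marker panels are drawn on
independent genealogies:

* 44 biallelic SNP loci.  With mu = 1e-9 per site per generation the
  per-locus theta is ~4e-5 and unconditioned simulation yields virtually
  no polymorphism, so each SNP locus is simulated conditional on exactly
  one segregating site, placed on the genealogy with probability
  proportional to branch length (the fixed-S convention).
* 12 microsatellite (SSR) loci under the infinite-alleles model at
  mu = 1e-3 (or 1e-5): mutations are Poisson on branches and every
  mutation creates a globally novel allele; a gene copy carries the most
  recent mutation on its root path.

Climate is simulated as 19 mutually independent variables, each a linear
gradient along the deme chain plus Gaussian noise.  The signal-to-noise
ratio is calibrated by Monte-Carlo lookup so that the *expected* Mantel
correlation between a single variable's distance matrix and the deme
lattice-distance matrix equals a requested true_r; true_r = 0 means pure
noise.

Two experiments reproduce the simulation design: the congruence
experiment (Population-Graph congruence between marker types over
replicates) and the climate-Mantel experiment (per-marker Mantel
correlation between cGD and climate distance, and the SNP-SSR
difference).  Replicates whose Population Graph contains disjunct groups
are discarded, since their cGD matrices contain undefined values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import msprime
import numpy as np
import pandas as pd

from .io_formats import ClimateTable, GenotypeMatrix, GeoTable
from .popgraph import (
    conditional_genetic_distance,
    estimate_population_graph,
    mantel,
)
from .climate_prep import climate_distance, standardize

__all__ = [
    "SimConfig",
    "ExperimentSummary",
    "build_demography",
    "simulate_genealogy",
    "simulate_snp_dataset",
    "simulate_ssr_dataset",
    "simulate_climate",
    "run_congruence_experiment",
    "run_climate_mantel_experiment",
    "make_fixture",
]


@dataclass
class SimConfig:
    """Parameters of the stepping-stone simulation experiments."""

    n_demes: int = 10
    neighbor_scaled_migration: float = 2.5  # 2*N_e*m between adjacent demes
    effective_size: int = 10_000  # global N_e, split evenly across demes
    size_is_per_deme: bool = False  # True: effective_size is each deme's N_e
    diploids_per_deme: int = 10
    n_snp_loci: int = 44
    n_ssr_loci: int = 12
    mu_snp: float = 1e-9
    mu_ssr: float = 1e-3
    n_climate_vars: int = 19
    alpha: float = 0.05  # Population-Graph edge significance
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_demes, self.effective_size, self.diploids_per_deme) <= 0:
            raise ValueError("counts must be positive")
        if self.neighbor_scaled_migration < 0:
            raise ValueError("migration must be non-negative")
        if self.neighbor_scaled_migration == 0 and self.n_demes > 1:
            raise ValueError(
                "zero migration with multiple demes: lineages in different "
                "demes can never coalesce"
            )

    @property
    def deme_size(self) -> float:
        """Effective size of one deme."""
        if self.size_is_per_deme:
            return float(self.effective_size)
        return self.effective_size / self.n_demes

    @property
    def deme_labels(self) -> list[str]:
        width = len(str(self.n_demes - 1))
        return [f"P{i:0{width}d}" for i in range(self.n_demes)]


@dataclass
class ExperimentSummary:
    per_replicate: pd.DataFrame
    summary: dict[str, float]
    n_reps: int
    n_used: int
    n_discarded: int
    config: dict
    observed_quantile: float | None = None


def build_demography(cfg: SimConfig) -> msprime.Demography:
    """One-dimensional chain of demes with nearest-neighbour migration."""
    dem = msprime.Demography()
    for i in range(cfg.n_demes):
        dem.add_population(name=f"d{i}", initial_size=cfg.deme_size)
    m = cfg.neighbor_scaled_migration / (2.0 * cfg.deme_size)
    for i in range(cfg.n_demes - 1):
        dem.set_migration_rate(f"d{i}", f"d{i + 1}", m)
        dem.set_migration_rate(f"d{i + 1}", f"d{i}", m)
    return dem


def _child_seeds(seed: int | None, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(1, 2**31 - 1, size=n)


def simulate_genealogy(cfg: SimConfig, seed: int | None = None):
    """A single-locus genealogy (tskit tree sequence) under the chain model."""
    (s,) = _child_seeds(seed, 1)
    dem = build_demography(cfg)
    samples = {f"d{i}": cfg.diploids_per_deme for i in range(cfg.n_demes)}
    return msprime.sim_ancestry(
        samples=samples, demography=dem, ploidy=2, random_seed=int(s)
    )


def _ancestry_replicates(cfg: SimConfig, n_loci: int, seed: int):
    dem = build_demography(cfg)
    samples = {f"d{i}": cfg.diploids_per_deme for i in range(cfg.n_demes)}
    return msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        ploidy=2,
        num_replicates=n_loci,
        random_seed=int(seed),
    )


def _individual_layout(cfg: SimConfig, ts) -> tuple[list[str], dict[str, str], list]:
    """Individual ids, population map, and per-individual node pairs."""
    labels = cfg.deme_labels
    ids: list[str] = []
    pop_of: dict[str, str] = {}
    node_pairs = []
    per_deme_count = [0] * cfg.n_demes
    for ind in ts.individuals():
        deme = ts.node(ind.nodes[0]).population
        name = f"{labels[deme]}_i{per_deme_count[deme]:02d}"
        per_deme_count[deme] += 1
        ids.append(name)
        pop_of[name] = labels[deme]
        node_pairs.append(tuple(ind.nodes))
    return ids, pop_of, node_pairs


def _place_single_site(ts, rng: np.random.Generator) -> np.ndarray:
    """Derived-allele indicator per sample for one fixed-S mutation.

    The branch carrying the mutation is chosen with probability
    proportional to its length, so the resulting site follows the neutral
    infinite-sites frequency spectrum for this genealogy.
    """
    tree = ts.first()
    nodes = []
    lengths = []
    for u in tree.nodes():
        bl = tree.branch_length(u)
        if bl > 0:
            nodes.append(u)
            lengths.append(bl)
    lengths = np.asarray(lengths)
    chosen = nodes[rng.choice(len(nodes), p=lengths / lengths.sum())]
    derived = np.zeros(ts.num_samples, dtype=np.int8)
    sample_index = {s: i for i, s in enumerate(ts.samples())}
    for s in tree.samples(chosen):
        derived[sample_index[s]] = 1
    return derived


def simulate_snp_dataset(cfg: SimConfig, seed: int | None = None) -> GenotypeMatrix:
    """Simulate ``cfg.n_snp_loci`` fixed-S biallelic loci as a GenotypeMatrix."""
    s_anc, s_mut = _child_seeds(seed, 2)
    rng = np.random.default_rng(s_mut)
    reps = _ancestry_replicates(cfg, cfg.n_snp_loci, s_anc)
    return _snp_matrix_from_ancestries(cfg, list(reps), rng)


def _snp_matrix_from_ancestries(cfg, ts_list, rng) -> GenotypeMatrix:
    first = ts_list[0]
    ids, pop_of, node_pairs = _individual_layout(cfg, first)
    sample_order = {s: i for i, s in enumerate(first.samples())}
    calls = np.empty((len(ids), len(ts_list)), dtype=object)
    for j, ts in enumerate(ts_list):
        derived = _place_single_site(ts, rng)
        for i, (na, nb) in enumerate(node_pairs):
            calls[i, j] = (
                str(derived[sample_order[na]]),
                str(derived[sample_order[nb]]),
            )
    loci = [f"snp{j:03d}" for j in range(len(ts_list))]
    return GenotypeMatrix("SNP", loci, ids, pop_of, calls)


def simulate_ssr_dataset(
    cfg: SimConfig, mu: float | None = None, seed: int | None = None
) -> GenotypeMatrix:
    """Simulate ``cfg.n_ssr_loci`` infinite-alleles loci as a GenotypeMatrix."""
    if mu is None:
        mu = cfg.mu_ssr
    if mu < 0:
        raise ValueError("mutation rate must be non-negative")
    s_anc, s_mut = _child_seeds(seed, 2)
    reps = _ancestry_replicates(cfg, cfg.n_ssr_loci, s_anc)
    mut_seeds = _child_seeds(int(s_mut), cfg.n_ssr_loci)
    return _ssr_matrix_from_ancestries(cfg, list(reps), mu, mut_seeds)


def _ssr_matrix_from_ancestries(cfg, ts_list, mu, mut_seeds) -> GenotypeMatrix:
    first = ts_list[0]
    ids, pop_of, node_pairs = _individual_layout(cfg, first)
    sample_order = {s: i for i, s in enumerate(first.samples())}
    calls = np.empty((len(ids), len(ts_list)), dtype=object)
    for j, ts in enumerate(ts_list):
        alleles = _iam_alleles(ts, mu, int(mut_seeds[j]))
        for i, (na, nb) in enumerate(node_pairs):
            calls[i, j] = (
                alleles[sample_order[na]],
                alleles[sample_order[nb]],
            )
    loci = [f"ssr{j:02d}" for j in range(len(ts_list))]
    return GenotypeMatrix("SSR", loci, ids, pop_of, calls)


def _iam_alleles(ts, mu: float, seed: int) -> list[str]:
    """Infinite-alleles state per sample: Poisson mutations on branches,
    each creating a novel allele; a sample carries its most recent one."""
    if mu == 0:
        return ["0"] * ts.num_samples
    mts = msprime.sim_mutations(
        ts, rate=mu, model=msprime.InfiniteAlleles(), random_seed=seed
    )
    if mts.num_sites == 0:
        return ["0"] * mts.num_samples
    v = next(mts.variants())
    return [v.alleles[g] for g in v.genotypes]


# ---------------------------------------------------------------------------
# climate simulation


_CALIBRATION_DRAWS = 10_000


def _expected_mantel(
    n_demes: int, n_vars: int, slope: float, eps: np.ndarray
) -> float:
    """Mean Mantel r between the multivariate climate distance and lattice
    distance for a given signal slope.

    Each draw builds ``n_vars`` independent variables a*position + noise,
    standardizes them across demes, and takes the Euclidean distance —
    exactly the construction the experiments feed to the Mantel test.
    ``eps`` is a (draws x n_demes x n_vars) noise block shared across
    candidate slopes (common random numbers keep the curve smooth).
    """
    pos = np.arange(n_demes, dtype=float)
    iu = np.triu_indices(n_demes, 1)
    lat = np.abs(pos[:, None] - pos[None, :])[iu]
    lat_c = lat - lat.mean()
    lat_norm = np.sqrt((lat_c**2).sum())
    v = slope * pos[None, :, None] + eps  # draws x demes x vars
    v = v - v.mean(axis=1, keepdims=True)
    v = v / v.std(axis=1, ddof=1, keepdims=True)
    dv = np.sqrt(((v[:, iu[0], :] - v[:, iu[1], :]) ** 2).sum(axis=2))
    dv_c = dv - dv.mean(axis=1, keepdims=True)
    denom = np.sqrt((dv_c**2).sum(axis=1)) * lat_norm
    r = (dv_c @ lat_c) / denom
    return float(r.mean())


_calibration_cache: dict[tuple[int, int, float], float] = {}


def calibrate_climate_slope(
    n_demes: int,
    true_r: float,
    n_vars: int = 19,
    n_draws: int = _CALIBRATION_DRAWS,
) -> float:
    """Signal slope a (noise sd fixed at 1) calibrating the climate set.

    The slope is chosen by bisection on a Monte-Carlo estimate (fixed
    noise stream) so that the *expected* Mantel correlation between the
    Euclidean distance over all ``n_vars`` standardized variables and the
    deme lattice distance equals ``true_r``.  Results are cached per
    (n_demes, n_vars, true_r).
    """
    if not 0.0 <= true_r <= 0.95:
        raise ValueError("true_r must be in [0, 0.95]")
    if true_r == 0.0:
        return 0.0
    key = (n_demes, n_vars, round(true_r, 6))
    if key in _calibration_cache:
        return _calibration_cache[key]
    rng = np.random.default_rng(20_090_400 + n_demes)
    eps = rng.standard_normal((n_draws, n_demes, n_vars))
    base = _expected_mantel(n_demes, n_vars, 0.0, eps)
    if base >= true_r:
        raise ValueError(f"calibration failure: true_r={true_r} below noise floor")
    lo, hi = 0.0, 1.0
    while _expected_mantel(n_demes, n_vars, hi, eps) < true_r:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError(f"calibration failure: true_r={true_r} unreachable")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _expected_mantel(n_demes, n_vars, mid, eps) < true_r:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    _calibration_cache[key] = a
    return a


def simulate_climate(
    n_demes: int,
    true_r: float,
    n_vars: int = 19,
    seed: int | None = None,
    labels: list[str] | None = None,
) -> ClimateTable:
    """Independent climate variables with a calibrated spatial gradient.

    Each variable is value(deme) = a*position + N(0, 1), with the shared
    slope ``a`` chosen so the expected Mantel correlation between the
    Euclidean distance over the standardized variable set and the deme
    lattice distance equals ``true_r`` (0 = pure noise).
    """
    a = calibrate_climate_slope(n_demes, true_r, n_vars=n_vars)
    rng = np.random.default_rng(seed)
    pos = np.arange(n_demes, dtype=float)
    values = a * pos[:, None] + rng.standard_normal((n_demes, n_vars))
    if labels is None:
        width = len(str(n_demes - 1))
        labels = [f"P{i:0{width}d}" for i in range(n_demes)]
    cols = [f"bio{i + 1}" for i in range(n_vars)]
    return ClimateTable(pd.DataFrame(values, index=labels, columns=cols))


# ---------------------------------------------------------------------------
# experiments


def _graph_cgd(gm: GenotypeMatrix, alpha: float):
    """Population Graph cGD matrix, or None when the replicate must be
    discarded (disjunct groups or no significant edges)."""
    try:
        graph = estimate_population_graph(gm, alpha=alpha)
    except ValueError:
        return None
    cgd = conditional_genetic_distance(graph)
    if not cgd.is_connected:
        return None
    return cgd


def run_congruence_experiment(
    cfg: SimConfig,
    n_reps: int = 1000,
    observed_r: float | None = None,
    seed: int | None = None,
    progress: bool = False,
) -> ExperimentSummary:
    """Distribution of Population-Graph congruence between marker types.

    Each replicate simulates an SNP and an SSR dataset on independent
    genealogies from the same demography, estimates a Population Graph for
    each, and records the Mantel correlation between the two cGD matrices.
    Replicates with a disconnected graph are discarded.
    """
    if seed is None:
        seed = cfg.seed
    seeds = _child_seeds(seed, 2 * n_reps).reshape(n_reps, 2)
    rows = []
    n_discarded = 0
    for rep in range(n_reps):
        gm_snp = simulate_snp_dataset(cfg, seed=int(seeds[rep, 0]))
        gm_ssr = simulate_ssr_dataset(cfg, seed=int(seeds[rep, 1]))
        cgd_a = _graph_cgd(gm_snp, cfg.alpha)
        cgd_b = _graph_cgd(gm_ssr, cfg.alpha)
        if cgd_a is None or cgd_b is None:
            n_discarded += 1
            continue
        r, _ = mantel(cgd_a, cgd_b, n_perm=0)
        rows.append((rep, r))
    _check_discards(n_discarded, n_reps)
    df = pd.DataFrame(rows, columns=["replicate", "r"])
    rs = df["r"].to_numpy()
    summary = {
        "mean_r": float(rs.mean()),
        "sd_r": float(rs.std(ddof=1)),
        "q2.5": float(np.percentile(rs, 2.5)),
        "q97.5": float(np.percentile(rs, 97.5)),
    }
    quantile = None
    if observed_r is not None:
        quantile = (1 + int((rs <= observed_r).sum())) / (len(rs) + 1)
    return ExperimentSummary(
        df, summary, n_reps, len(rs), n_discarded, asdict(cfg), quantile
    )


def run_climate_mantel_experiment(
    cfg: SimConfig,
    true_r: float,
    n_reps: int = 1000,
    observed_diff: float | None = None,
    seed: int | None = None,
) -> ExperimentSummary:
    """Per-marker Mantel correlation between cGD and climate distance.

    Climate is redrawn each replicate at the requested true structure-
    climate correlation; the per-replicate record holds the SNP and SSR
    Mantel r values and their difference (SNP - SSR).
    """
    if seed is None:
        seed = cfg.seed
    # fail fast and warm the calibration cache
    calibrate_climate_slope(cfg.n_demes, true_r, n_vars=cfg.n_climate_vars)
    seeds = _child_seeds(seed, 3 * n_reps).reshape(n_reps, 3)
    rows = []
    n_discarded = 0
    for rep in range(n_reps):
        gm_snp = simulate_snp_dataset(cfg, seed=int(seeds[rep, 0]))
        gm_ssr = simulate_ssr_dataset(cfg, seed=int(seeds[rep, 1]))
        cgd_a = _graph_cgd(gm_snp, cfg.alpha)
        cgd_b = _graph_cgd(gm_ssr, cfg.alpha)
        if cgd_a is None or cgd_b is None:
            n_discarded += 1
            continue
        climate = simulate_climate(
            cfg.n_demes,
            true_r,
            n_vars=cfg.n_climate_vars,
            seed=int(seeds[rep, 2]),
            labels=cfg.deme_labels,
        )
        cdist = climate_distance(standardize(climate))
        r_snp, _ = mantel(cgd_a, cdist, n_perm=0)
        r_ssr, _ = mantel(cgd_b, cdist, n_perm=0)
        rows.append((rep, r_snp, r_ssr, r_snp - r_ssr))
    _check_discards(n_discarded, n_reps)
    df = pd.DataFrame(rows, columns=["replicate", "r_snp", "r_ssr", "diff"])
    summary = {
        "true_r": true_r,
        "mean_r_snp": float(df["r_snp"].mean()),
        "mean_r_ssr": float(df["r_ssr"].mean()),
        "bias_snp": float(df["r_snp"].mean() - true_r),
        "bias_ssr": float(df["r_ssr"].mean() - true_r),
        "mean_diff": float(df["diff"].mean()),
        "sd_diff": float(df["diff"].std(ddof=1)),
        "q2.5_diff": float(np.percentile(df["diff"], 2.5)),
        "q97.5_diff": float(np.percentile(df["diff"], 97.5)),
    }
    quantile = None
    if observed_diff is not None:
        d = df["diff"].to_numpy()
        quantile = (1 + int((d <= observed_diff).sum())) / (len(d) + 1)
    return ExperimentSummary(
        df, summary, n_reps, len(df), n_discarded, asdict(cfg), quantile
    )


def _check_discards(n_discarded: int, n_reps: int) -> None:
    if n_discarded > 0.5 * n_reps:
        raise RuntimeError(
            f"{n_discarded}/{n_reps} replicates discarded (disconnected or "
            "empty Population Graphs); check migration and sample sizes"
        )


# ---------------------------------------------------------------------------
# packaged toy fixture


def make_fixture(seed: int, out_dir=None) -> dict:
    """Small deterministic dataset for tests: 4 demes x 10 diploids,
    12 SSR + 20 SNP loci, climate and coordinates.

    Returns a dict of in-memory objects; if ``out_dir`` is given the same
    content is also written as CSV files (byte-identical per seed).
    """
    cfg = SimConfig(
        n_demes=4,
        n_snp_loci=20,
        n_ssr_loci=12,
        seed=seed,
    )
    s_snp, s_ssr, s_clim = (int(s) for s in _child_seeds(seed, 3))
    gm_snp = simulate_snp_dataset(cfg, seed=s_snp)
    gm_ssr = simulate_ssr_dataset(cfg, seed=s_ssr)
    climate = simulate_climate(
        cfg.n_demes, true_r=0.4, seed=s_clim, labels=cfg.deme_labels
    )
    # demes evenly spaced on a line running northeast
    coords = pd.DataFrame(
        {
            "longitude": [-80.0 + 1.5 * i for i in range(cfg.n_demes)],
            "latitude": [40.0 + 1.0 * i for i in range(cfg.n_demes)],
        },
        index=cfg.deme_labels,
    )
    geo = GeoTable(coords)
    out = {"snp": gm_snp, "ssr": gm_ssr, "climate": climate, "geo": geo, "config": cfg}
    if out_dir is not None:
        from pathlib import Path

        from .io_formats import (
            write_climate_table,
            write_genotype_table,
            write_geo_table,
        )

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_genotype_table(gm_snp, out_dir / "fixture_snp.csv")
        write_genotype_table(gm_ssr, out_dir / "fixture_ssr.csv")
        write_climate_table(climate, out_dir / "fixture_climate.csv")
        write_geo_table(geo, out_dir / "fixture_coords.csv")
    return out
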
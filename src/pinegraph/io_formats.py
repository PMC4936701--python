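"""Tabular input/output for genotype, coordinate, climate, and distance data.

All on-disk formats are plain UTF-8 CSV with "." as the decimal separator:

* genotype tables: columns ``population, individual, <locus>, <locus>, ...``
  with diploid calls written ``"a1/a2"`` and missing data written ``"NA"``;
* coordinate tables: columns ``population, longitude, latitude`` (degrees,
  negative longitude = west);
* climate tables: a ``population`` column followed by one named column per
  climate variable;
* distance matrices: square CSV whose first row and first column carry the
  same ordered population labels.

Allele codes are treated as opaque strings throughout: microsatellite
fragment lengths are identifiers, never quantities, which is all an
infinite-alleles analysis requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = "NA"

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "GeoTable",
    "ClimateTable",
    "DistanceMatrix",
    "read_genotype_table",
    "write_genotype_table",
    "read_geo_table",
    "write_geo_table",
    "read_climate_table",
    "write_climate_table",
    "filter_snp_loci",
    "read_matrix",
    "write_matrix",
    "load_pine_coordinates",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect or invariants."""


@dataclass
class GenotypeMatrix:
    """Diploid multi-locus genotypes with population labels.

    ``calls`` is an (individuals x loci) object array whose entries are
    either a 2-tuple of allele-code strings or ``None`` for missing data.
    ``gene_of_locus`` optionally maps each locus to a gene/contig label so
    locus pairs can be classified as intragenic versus intergenic.
    """

    marker_type: str  # "SSR" or "SNP"
    locus_ids: list[str]
    individual_ids: list[str]
    population_of_individual: dict[str, str]
    calls: np.ndarray
    gene_of_locus: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.marker_type not in ("SSR", "SNP"):
            raise FormatError(f"unknown marker_type {self.marker_type!r}")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise FormatError("duplicate locus identifiers")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise FormatError("duplicate individual identifiers")
        if self.calls.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise FormatError("calls array shape does not match ids")
        for ind in self.individual_ids:
            if ind not in self.population_of_individual:
                raise FormatError(f"individual {ind!r} has no population label")
        if self.marker_type == "SNP":
            for j, locus in enumerate(self.locus_ids):
                alleles = self.alleles_at(j)
                if len(alleles) > 2:
                    raise FormatError(
                        f"SNP locus {locus!r} carries {len(alleles)} alleles "
                        f"({sorted(alleles)}); at most 2 allowed"
                    )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def populations(self) -> list[str]:
        """Population labels in lexicographic order."""
        return sorted(set(self.population_of_individual.values()))

    def individuals_of(self, population: str) -> list[int]:
        return [
            i
            for i, ind in enumerate(self.individual_ids)
            if self.population_of_individual[ind] == population
        ]

    def alleles_at(self, locus_index: int) -> set[str]:
        out: set[str] = set()
        for call in self.calls[:, locus_index]:
            if call is not None:
                out.update(call)
        return out

    def subset_loci(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.locus_ids.index(l) for l in keep]
        gene = None
        if self.gene_of_locus is not None:
            gene = {l: self.gene_of_locus[l] for l in keep if l in self.gene_of_locus}
        return replace(
            self,
            locus_ids=list(keep),
            calls=self.calls[:, idx],
            gene_of_locus=gene,
        )


@dataclass
class GeoTable:
    """Population coordinates in decimal degrees."""

    table: pd.DataFrame  # index = population, columns = longitude, latitude

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dups = sorted(t.index[t.index.duplicated()])
            raise FormatError(f"duplicate populations: {dups}")
        if (t["latitude"].abs() > 90).any():
            bad = t.index[t["latitude"].abs() > 90].tolist()
            raise FormatError(f"latitude out of range for {bad}")
        if (t["longitude"].abs() > 180).any():
            bad = t.index[t["longitude"].abs() > 180].tolist()
            raise FormatError(f"longitude out of range for {bad}")

    @property
    def populations(self) -> list[str]:
        return list(self.table.index)


@dataclass
class ClimateTable:
    """Per-population climate variables, optionally standardized."""

    table: pd.DataFrame  # index = population, columns = variables
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            bad = self.table.columns[self.table.isna().any()].tolist()
            raise FormatError(f"missing climate values in columns {bad}")
        if self.standardized:
            means = self.table.mean(axis=0)
            sds = self.table.std(axis=0, ddof=1)
            if (means.abs() > 1e-8).any() or ((sds - 1).abs() > 1e-8).any():
                raise FormatError("standardized flag set but columns are not z-scores")

    @property
    def populations(self) -> list[str]:
        return list(self.table.index)

    @property
    def variables(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal.

    Disconnected pairs (e.g. populations in different components of a
    Population Graph) are stored as ``np.nan``.
    """

    labels: list[str]
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if v.shape != (k, k):
            raise FormatError("distance matrix shape does not match labels")
        if len(set(self.labels)) != k:
            raise FormatError("duplicate labels in distance matrix")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(v - v.T)) if k else 0.0
        if k and asym > 1e-9:
            raise FormatError(f"matrix asymmetric (max |d_ij - d_ji| = {asym:.3g})")
        if k and np.nanmax(np.abs(np.diag(v))) > 1e-12:
            raise FormatError("nonzero diagonal in distance matrix")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def is_connected(self) -> bool:
        return not np.isnan(self.values).any()

    def condensed(self) -> np.ndarray:
        """Off-diagonal upper-triangle entries in row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# genotype tables


def _parse_call(token: str, row_label: str, locus: str) -> tuple[str, str] | None:
    token = token.strip()
    if token == MISSING:
        return None
    parts = token.split("/")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise FormatError(
            f"malformed call {token!r} at individual {row_label!r}, locus {locus!r}"
        )
    return (parts[0], parts[1])


def read_genotype_table(path, marker_type: str) -> GenotypeMatrix:
    """Read a diploid genotype CSV (see module docstring for the dialect)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["population", "individual"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"genotype table lacks required column {col!r}")
    loci = [c for c in df.columns if c not in required]
    if not loci:
        raise FormatError("genotype table has no locus columns")
    individuals = df["individual"].tolist()
    if len(set(individuals)) != len(individuals):
        dups = sorted({i for i in individuals if individuals.count(i) > 1})
        raise FormatError(f"duplicate individual IDs: {dups}")
    calls = np.empty((len(df), len(loci)), dtype=object)
    for i, row in df.iterrows():
        for j, locus in enumerate(loci):
            calls[i, j] = _parse_call(row[locus], row["individual"], locus)
    pops = dict(zip(individuals, df["population"]))
    return GenotypeMatrix(marker_type, loci, individuals, pops, calls)


def write_genotype_table(gm: GenotypeMatrix, path) -> None:
    rows = []
    for i, ind in enumerate(gm.individual_ids):
        row: dict[str, str] = {
            "population": gm.population_of_individual[ind],
            "individual": ind,
        }
        for j, locus in enumerate(gm.locus_ids):
            call = gm.calls[i, j]
            row[locus] = MISSING if call is None else f"{call[0]}/{call[1]}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def filter_snp_loci(
    gm: GenotypeMatrix, min_call_rate: float = 0.80, min_maf: float = 0.01
) -> GenotypeMatrix:
    """Drop SNP loci with low call rate or low pooled minor-allele frequency.

    The panel is filtered once over the pooled dataset: call rate is the
    fraction of non-missing calls across all individuals, and the minor
    allele frequency is computed over all non-missing gene copies pooled
    across populations.  Loci are kept only if call rate > ``min_call_rate``
    and MAF > ``min_maf``.
    """
    if gm.marker_type != "SNP":
        raise FormatError("filter_snp_loci applies to SNP panels only")
    keep: list[str] = []
    for j, locus in enumerate(gm.locus_ids):
        col = gm.calls[:, j]
        non_missing = [c for c in col if c is not None]
        call_rate = len(non_missing) / gm.n_individuals
        if call_rate <= min_call_rate:
            continue
        counts: dict[str, int] = {}
        for a, b in non_missing:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        total = sum(counts.values())
        maf = 0.0 if len(counts) < 2 else min(counts.values()) / total
        if maf <= min_maf:
            continue
        keep.append(locus)
    if not keep:
        raise FormatError("no loci survive filters")
    return gm.subset_loci(keep)


# ---------------------------------------------------------------------------
# coordinates and climate


def read_geo_table(path) -> GeoTable:
    df = pd.read_csv(path)
    for col in ("population", "longitude", "latitude"):
        if col not in df.columns:
            raise FormatError(f"coordinate table lacks column {col!r}")
    df = df.set_index("population")[["longitude", "latitude"]].astype(float)
    return GeoTable(df)


def write_geo_table(geo: GeoTable, path) -> None:
    geo.table.rename_axis("population").reset_index().to_csv(path, index=False)


def read_climate_table(path, geo: GeoTable | None = None) -> ClimateTable:
    df = pd.read_csv(path)
    if "population" not in df.columns:
        raise FormatError("climate table lacks a 'population' column")
    df = df.set_index("population").astype(float)
    ct = ClimateTable(df, standardized=False)
    if geo is not None:
        diff = set(ct.populations) ^ set(geo.populations)
        if diff:
            warnings.warn(
                f"climate/coordinate population sets differ: {sorted(diff)}",
                stacklevel=2,
            )
    return ct


def write_climate_table(ct: ClimateTable, path) -> None:
    ct.table.rename_axis("population").reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# distance matrices


def write_matrix(dm: DistanceMatrix, path) -> None:
    dm.to_frame().rename_axis("population").to_csv(path, float_format="%.17g")


def read_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    labels_r = [str(l) for l in df.index]
    labels_c = [str(c) for c in df.columns]
    if labels_r != labels_c:
        raise FormatError("row and column labels differ in distance matrix")
    return DistanceMatrix(labels_r, df.to_numpy(dtype=float))


def load_pine_coordinates() -> GeoTable:
    """Coordinates of the 29 sampled eastern white pine populations."""
    from importlib.resources import files

    path = files("pinegraph.data").joinpath("pine_coordinates.csv")
    with path.open("rb") as fh:
        return read_geo_table(fh)
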
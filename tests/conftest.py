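"""Shared fixtures: small hand-built genotype panels and a simulated toy."""

from __future__ import annotations

import numpy as np
import pytest

from pinegraph.io_formats import GenotypeMatrix
from pinegraph.coalsim import make_fixture


def build_genotype_matrix(
    rows: list[tuple[str, str, list[str | None]]],
    loci: list[str],
    marker_type: str = "SNP",
    gene_of_locus: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """rows: (population, individual, ["a/b" or None per locus])."""
    calls = np.empty((len(rows), len(loci)), dtype=object)
    individuals = []
    pops = {}
    for i, (pop, ind, genos) in enumerate(rows):
        individuals.append(ind)
        pops[ind] = pop
        for j, g in enumerate(genos):
            calls[i, j] = None if g is None else tuple(g.split("/"))
    return GenotypeMatrix(marker_type, loci, individuals, pops, calls, gene_of_locus)


@pytest.fixture(scope="session")
def two_pop_toy() -> GenotypeMatrix:
    """Two populations of two diploids at one biallelic locus.

    Allele counts chosen so the Weir-Cockerham components can be verified
    by hand: p = 3/4 vs 1/4, one heterozygote per population.
    """
    return build_genotype_matrix(
        [
            ("p1", "i1", ["A/A"]),
            ("p1", "i2", ["A/a"]),
            ("p2", "i3", ["a/a"]),
            ("p2", "i4", ["A/a"]),
        ],
        loci=["L1"],
    )


@pytest.fixture(scope="session")
def sim_toy() -> dict:
    """Deterministic 4-deme simulated dataset (SNP + SSR + climate + geo)."""
    return make_fixture(seed=20_240_101)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
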
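"""Shared fixtures: tiny hand-built genotype datasets and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from popcompare.genotype_core import GenotypeDataset, PopulationSite


def make_dataset(pop_genotypes: dict[str, list[list[tuple[int, int]]]],
                 loci: list[str] | None = None,
                 sites: list[PopulationSite] | None = None) -> GenotypeDataset:
    """Build a dataset from {pop: [per-individual genotype pair lists]}."""
    first = next(iter(pop_genotypes.values()))
    n_loci = len(first[0])
    loci = loci or [f"L{j + 1}" for j in range(n_loci)]
    rows, ids, pops = [], [], []
    for pop, inds in pop_genotypes.items():
        for k, g in enumerate(inds):
            rows.append([[a, b] for a, b in g])
            ids.append(f"{pop}_{k + 1}")
            pops.append(pop)
    return GenotypeDataset(loci, np.array(rows), ids, pops, sites)


@pytest.fixture
def two_pop_one_locus() -> GenotypeDataset:
    """2 pops x 4 individuals x 1 locus with gene counts {A:6,B:2} vs {A:2,B:6}."""
    return make_dataset(
        {
            "p1": [[(1, 1)], [(1, 1)], [(1, 1)], [(1, 2)]],
            "p2": [[(2, 2)], [(2, 2)], [(2, 2)], [(1, 1)]],
        }
    )


@pytest.fixture
def fixed_difference() -> GenotypeDataset:
    """Two populations fixed for different alleles at every locus."""
    return make_dataset(
        {
            "p1": [[(1, 1), (3, 3)]] * 3,
            "p2": [[(2, 2), (4, 4)]] * 3,
        }
    )
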
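"""Per-locus / per-population diversity statistics and multiple-testing control.

Implements the classical microsatellite diversity panel:

* allelic richness ``A`` (distinct alleles observed),
* rarefied allelic richness ``A_R`` — the expected number of distinct alleles
  in a random subsample of ``g`` genes, which removes the sample-size bias of
  raw allele counts (Kalinowski-style single-level rarefaction; the pipeline
  standardizes to ``g = 4`` genes, the smallest sample across populations),
* observed heterozygosity ``H_O``,
* Nei's unbiased expected heterozygosity ``uH_E = 2n/(2n-1) (1 - sum p_i^2)``,
* Holm's sequential Bonferroni correction,

plus the table builder mirroring the per-site diversity report (watershed,
population, n, A, A_R, H_O, uH_E with per-cohort mean ± SE rows).

Undefined statistics (empty samples, rarefaction with ``g`` exceeding the
sample) propagate as ``NaN`` markers, never as zeros.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_core import ALL, MISSING, GenotypeDataset, allele_counts
from .hwe import (  # noqa: F401  (re-exported: HWE is part of the diversity surface)
    ChainSettings,
    HWEResult,
    genotype_counts,
    hwe_exact_enumeration,
    hwe_exact_test,
    hwe_test_dataset,
)

__all__ = [
    "UndefinedStatistic",
    "allelic_richness",
    "rarefied_allelic_richness",
    "observed_heterozygosity",
    "unbiased_expected_heterozygosity",
    "sequential_bonferroni",
    "diversity_table",
    "ChainSettings",
    "HWEResult",
    "genotype_counts",
    "hwe_exact_test",
    "hwe_exact_enumeration",
    "hwe_test_dataset",
]


class UndefinedStatistic(ValueError):
    """A statistic is undefined for the given sample (e.g. no typed genes)."""


def _total(counts: Mapping[int, int]) -> int:
    return int(sum(counts.values()))


def allelic_richness(counts: Mapping[int, int]) -> int:
    """Number of distinct alleles with positive count."""
    if _total(counts) == 0:
        raise UndefinedStatistic("no typed genes")
    return sum(1 for c in counts.values() if c > 0)


def rarefied_allelic_richness(counts: Mapping[int, int], g: int = 4) -> float:
    """Expected distinct-allele count in a random ``g``-gene subsample.

    ``sum_i [1 - C(N - N_i, g) / C(N, g)]`` over alleles with count ``N_i``,
    ``N`` the total genes.  Equals the plain allele count when ``g = N``.

    Raises
    ------
    UndefinedStatistic
        If ``g`` exceeds the number of typed genes (callers skip the
        population with a warning rather than zero-filling) or ``g < 2``.
    """
    N = _total(counts)
    if g < 2:
        raise UndefinedStatistic(f"rarefaction needs g >= 2, got {g}")
    if g > N:
        raise UndefinedStatistic(f"rarefaction to {g} genes but only {N} typed")
    total = 0.0
    for Ni in counts.values():
        if Ni <= 0:
            continue
        # C(N-Ni, g)/C(N, g) = prod_{j<g} (N-Ni-j)/(N-j), zero when N-Ni < g
        if N - Ni < g:
            total += 1.0
        else:
            ratio = 1.0
            for j in range(g):
                ratio *= (N - Ni - j) / (N - j)
            total += 1.0 - ratio
    return total


def observed_heterozygosity(
    ds: GenotypeDataset, locus: str, population: str = ALL
) -> float:
    """Fraction of typed individuals whose two alleles differ."""
    j = ds.locus_index(locus)
    calls = ds.alleles[:, j, :] if population == ALL else ds.alleles[ds.pop_mask(population), j, :]
    typed = calls[calls[:, 0] != MISSING]
    if len(typed) == 0:
        raise UndefinedStatistic(f"no typed individuals at {locus!r}")
    return float(np.mean(typed[:, 0] != typed[:, 1]))


def unbiased_expected_heterozygosity(counts: Mapping[int, int]) -> float:
    """Nei's small-sample-corrected gene diversity ``2n/(2n-1) (1 - sum p^2)``."""
    N = _total(counts)  # genes = 2n
    if N < 2:
        raise UndefinedStatistic("need at least 2 typed genes")
    p2 = sum((c / N) ** 2 for c in counts.values())
    return (N / (N - 1)) * (1.0 - p2)


def sequential_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Holm's step-down procedure; flags returned in input order.

    Sort ascending; reject while ``p_(i) <= alpha / (m - i + 1)``; the first
    failure stops the sequence.
    """
    m = len(p_values)
    if m == 0:
        return []
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            flags[idx] = True
        else:
            break
    return flags.tolist()


# ---------------------------------------------------------------------------
# Report builder
# ---------------------------------------------------------------------------

def diversity_table(
    ds: GenotypeDataset,
    rarefaction_genes: int = 4,
    cohort: str = "",
) -> pd.DataFrame:
    """Per-population diversity summary in the standard report shape.

    One row per population: watershed group, population, cohort label, number
    of individuals, and across-locus means of A, A_R (rarefied to
    ``rarefaction_genes``), H_O and uH_E; a final ``mean ± SE`` row aggregates
    across populations.  A population whose smallest per-locus gene count is
    below ``rarefaction_genes`` gets ``NaN`` for A_R at the affected loci
    (skipped in the mean, recorded in the ``n_rarefaction_skipped`` column).
    """
    rows = []
    sizes = ds.sample_sizes()
    for pop in ds.populations:
        a_vals, ar_vals, ho_vals, uhe_vals = [], [], [], []
        skipped = 0
        for locus in ds.loci:
            counts = allele_counts(ds, locus, pop)
            if not counts:
                continue
            a_vals.append(allelic_richness(counts))
            try:
                ar_vals.append(rarefied_allelic_richness(counts, rarefaction_genes))
            except UndefinedStatistic:
                skipped += 1
            ho_vals.append(observed_heterozygosity(ds, locus, pop))
            try:
                uhe_vals.append(unbiased_expected_heterozygosity(counts))
            except UndefinedStatistic:
                pass
        site = ds.site(pop)
        rows.append(
            {
                "watershed": site.group_id,
                "population": pop,
                "cohort": cohort,
                "individuals": sizes[pop],
                "A": np.mean(a_vals) if a_vals else np.nan,
                "A_R": np.mean(ar_vals) if ar_vals else np.nan,
                "H_O": np.mean(ho_vals) if ho_vals else np.nan,
                "uH_E": np.mean(uhe_vals) if uhe_vals else np.nan,
                "n_rarefaction_skipped": skipped,
            }
        )
    df = pd.DataFrame(rows)
    agg = {
        "watershed": f"{df['watershed'].nunique()} watersheds",
        "population": f"{len(df)} populations",
        "cohort": cohort,
        "individuals": int(df["individuals"].sum()),
        "n_rarefaction_skipped": int(df["n_rarefaction_skipped"].sum()),
    }
    for col in ("A", "A_R", "H_O", "uH_E"):
        vals = df[col].dropna().to_numpy()
        agg[col] = vals.mean() if len(vals) else np.nan
        agg[f"{col}_se"] = (
            vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else np.nan
        )
    return pd.concat([df, pd.DataFrame([agg])], ignore_index=True)
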
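"""Hardy–Weinberg exact testing by Markov chain Monte Carlo, with an
enumeration oracle for small tables.

The null distribution is the classical conditional (Levene) distribution of
genotype arrays given the allele counts:

    P(array) = n! 2^H  prod_a N_a!  /  ( (2n)!  prod_{i<=j} n_ij! )

with ``n`` individuals, ``H`` heterozygotes, allele gene counts ``N_a`` and
genotype cell counts ``n_ij``.  The exact p-value is the total probability of
arrays no more probable than the observed one (ties included).

The chain operates on the 2n gene slots directly: each step proposes swapping
the contents of two uniformly chosen slots — a switch of two genotypes'
allele pairing that preserves allele counts exactly.  Random transpositions
leave the uniform distribution over gene arrangements invariant, and the
induced array distribution of a uniform arrangement is precisely the Levene
null, so no accept/reject correction is needed.  The p-value is the fraction
of sampled arrays whose conditional probability is at or below the observed
array's; its Monte Carlo standard error comes from batch means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .genotype_core import ALL, MISSING, GenotypeDataset

__all__ = [
    "ChainSettings",
    "HWEResult",
    "genotype_counts",
    "hwe_exact_test",
    "hwe_exact_enumeration",
    "hwe_test_dataset",
]

_LOG2 = math.log(2.0)
_TIE_TOL = 1e-7


@dataclass(frozen=True)
class ChainSettings:
    """Markov-chain schedule: burn-in, then ``batches`` x ``iterations_per_batch``
    recorded steps.  The defaults are the conventional heavy schedule
    (10,000 / 1,000 / 10,000); analyses on small tables may use far less."""

    dememorization: int = 10_000
    batches: int = 1_000
    iterations_per_batch: int = 10_000

    def __post_init__(self) -> None:
        if min(self.dememorization, self.batches, self.iterations_per_batch) < 1:
            raise ValueError("all chain settings must be positive")


@dataclass(frozen=True)
class HWEResult:
    locus: str
    scope: str
    p_value: float
    mc_se: float
    chain_settings: ChainSettings | None
    testable: bool = True
    n_individuals: int = 0
    note: str = ""


def genotype_counts(
    ds: GenotypeDataset, locus: str, population: str = ALL
) -> dict[tuple[int, int], int]:
    """Genotype cell counts (sorted allele pairs) over non-missing calls."""
    j = ds.locus_index(locus)
    calls = ds.alleles[:, j, :] if population == ALL else ds.alleles[ds.pop_mask(population), j, :]
    typed = calls[calls[:, 0] != MISSING]
    out: dict[tuple[int, int], int] = {}
    for a, b in np.sort(typed, axis=1):
        key = (int(a), int(b))
        out[key] = out.get(key, 0) + 1
    return out


def _log_weight(cnt: Mapping[tuple[int, int], int]) -> float:
    """Array-comparable part of log P(array): H log2 - sum log n_ij!."""
    lw = 0.0
    for (a, b), c in cnt.items():
        if c:
            if a != b:
                lw += c * _LOG2
            lw -= math.lgamma(c + 1)
    return lw


def _allele_gene_counts(cnt: Mapping[tuple[int, int], int]) -> dict[int, int]:
    out: dict[int, int] = {}
    for (a, b), c in cnt.items():
        out[a] = out.get(a, 0) + c
        out[b] = out.get(b, 0) + c
    return out


def hwe_exact_test(
    counts_by_genotype: Mapping[tuple[int, int], int],
    settings: ChainSettings | None = None,
    seed: int = 0,
    locus: str = "",
    scope: str = "",
) -> HWEResult:
    """Monte Carlo estimate of the exact HWE p-value for one genotype table.

    Monomorphic tables and tables with fewer than 3 individuals are not
    testable; they are returned with ``testable=False`` (conventionally
    counted as conforming downstream).
    """
    settings = settings or ChainSettings()
    cnt = {
        (min(a, b), max(a, b)): int(c)
        for (a, b), c in counts_by_genotype.items()
        if c > 0
    }
    n = sum(cnt.values())
    alleles = _allele_gene_counts(cnt)
    if len(alleles) < 2 or n < 3:
        why = "monomorphic" if len(alleles) < 2 else f"only {n} individuals"
        return HWEResult(locus, scope, math.nan, math.nan, settings,
                         testable=False, n_individuals=n, note=f"not testable: {why}")

    # gene slots: individual i occupies slots 2i, 2i+1
    genes: list[int] = []
    for (a, b), c in sorted(cnt.items()):
        genes.extend([a, b] * c)
    two_n = len(genes)
    log = math.log
    threshold = _log_weight(cnt) + _TIE_TOL

    rng = np.random.default_rng(seed)
    cur = dict(cnt)
    lw = _log_weight(cur)

    def run(steps: int, record: bool) -> int:
        nonlocal lw
        hits = 0
        slots = rng.integers(0, two_n, size=(steps, 2))
        for s1, s2 in slots:
            u, v = s1 >> 1, s2 >> 1
            if u != v:
                g1, g2 = genes[s1], genes[s2]
                if g1 != g2:
                    a0, a1 = genes[2 * u], genes[2 * u + 1]
                    b0, b1 = genes[2 * v], genes[2 * v + 1]
                    oc_u = (a0, a1) if a0 <= a1 else (a1, a0)
                    oc_v = (b0, b1) if b0 <= b1 else (b1, b0)
                    genes[s1] = g2
                    genes[s2] = g1
                    a0, a1 = genes[2 * u], genes[2 * u + 1]
                    b0, b1 = genes[2 * v], genes[2 * v + 1]
                    nc_u = (a0, a1) if a0 <= a1 else (a1, a0)
                    nc_v = (b0, b1) if b0 <= b1 else (b1, b0)
                    c = cur[oc_u]
                    cur[oc_u] = c - 1
                    lw += log(c)
                    c = cur[oc_v]
                    cur[oc_v] = c - 1
                    lw += log(c)
                    c = cur.get(nc_u, 0)
                    cur[nc_u] = c + 1
                    lw -= log(c + 1)
                    c = cur.get(nc_v, 0)
                    cur[nc_v] = c + 1
                    lw -= log(c + 1)
                    lw += _LOG2 * (
                        (nc_u[0] != nc_u[1])
                        + (nc_v[0] != nc_v[1])
                        - (oc_u[0] != oc_u[1])
                        - (oc_v[0] != oc_v[1])
                    )
            if record and lw <= threshold:
                hits += 1
        return hits

    run(settings.dememorization, record=False)
    batch_means = np.empty(settings.batches)
    for b in range(settings.batches):
        # resync the incrementally tracked log-weight to stop float drift
        lw = _log_weight(cur)
        hits = run(settings.iterations_per_batch, record=True)
        batch_means[b] = hits / settings.iterations_per_batch
    p = float(batch_means.mean())
    se = (
        float(batch_means.std(ddof=1) / math.sqrt(settings.batches))
        if settings.batches > 1
        else math.nan
    )
    return HWEResult(locus, scope, p, se, settings, testable=True, n_individuals=n)


# ---------------------------------------------------------------------------
# Enumeration oracle
# ---------------------------------------------------------------------------

def hwe_exact_enumeration(
    counts_by_genotype: Mapping[tuple[int, int], int]
) -> float:
    """Exact HWE p-value by full enumeration of genotype arrays.

    Enumerates every genotype array compatible with the observed allele
    counts, evaluates each array's Levene probability, and sums probability
    over arrays no more probable than the observed one.  Practical for small
    tables (2 alleles at any modest ``n``; 3+ alleles at small ``n``).
    """
    cnt = {
        (min(a, b), max(a, b)): int(c)
        for (a, b), c in counts_by_genotype.items()
        if c > 0
    }
    n = sum(cnt.values())
    allele_genes = _allele_gene_counts(cnt)
    alleles = sorted(allele_genes)
    k = len(alleles)
    if k < 2:
        raise ValueError("monomorphic table: exact test undefined")
    aidx = {a: i for i, a in enumerate(alleles)}
    target = [allele_genes[a] for a in alleles]
    cells = [(i, j) for i in range(k) for j in range(i, k)]
    # alleles appearing in cells from position t onward (for pruning)
    future = [set() for _ in range(len(cells) + 1)]
    for t in range(len(cells) - 1, -1, -1):
        i, j = cells[t]
        future[t] = future[t + 1] | {i, j}

    obs_lw = _log_weight(cnt)
    log_probs: list[float] = []
    hit_probs: list[float] = []

    def recurse(t: int, rem: list[int], n_rem: int, lw: float) -> None:
        if t == len(cells):
            if n_rem == 0 and all(r == 0 for r in rem):
                log_probs.append(lw)
                if lw <= obs_lw + _TIE_TOL:
                    hit_probs.append(lw)
            return
        i, j = cells[t]
        if i == j:
            cmax = rem[i] // 2
        else:
            cmax = min(rem[i], rem[j])
        cmax = min(cmax, n_rem)
        for c in range(cmax + 1):
            rem[i] -= c * (2 if i == j else 1)
            if i != j:
                rem[j] -= c
            ok = all(rem[a] == 0 for a in range(k) if a not in future[t + 1])
            if ok:
                d = lw - math.lgamma(c + 1) + (c * _LOG2 if i != j else 0.0)
                recurse(t + 1, rem, n_rem - c, d)
            rem[i] += c * (2 if i == j else 1)
            if i != j:
                rem[j] += c

    recurse(0, list(target), n, 0.0)
    # normalize: P(array) proportional to exp(lw); constants cancel
    lws = np.array(log_probs)
    mx = lws.max()
    total = np.exp(lws - mx).sum()
    if not hit_probs:
        return 0.0
    hits = np.exp(np.array(hit_probs) - mx).sum()
    return float(hits / total)


# ---------------------------------------------------------------------------
# Dataset-level driver
# ---------------------------------------------------------------------------

def hwe_test_dataset(
    ds: GenotypeDataset,
    settings: ChainSettings | None = None,
    seed: int = 0,
    scope: str = "island",
    min_individuals: int = 3,
) -> list[HWEResult]:
    """Exact HWE tests across loci.

    ``scope='island'`` pools all populations per locus (the Wahlund-sensitive
    island-wide test); ``scope='population'`` tests every locus x population
    cell.  Cells with fewer than ``min_individuals`` typed individuals are
    reported as not testable rather than silently dropped.
    """
    settings = settings or ChainSettings()
    ss = np.random.SeedSequence(seed)
    results: list[HWEResult] = []
    if scope == "island":
        units: list[tuple[str, str]] = [(locus, ALL) for locus in ds.loci]
    elif scope == "population":
        units = [(locus, pop) for locus in ds.loci for pop in ds.populations]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    children = ss.spawn(len(units))
    for (locus, pop), child in zip(units, children):
        cnt = genotype_counts(ds, locus, pop)
        n = sum(cnt.values())
        label = "island-wide" if pop == ALL else pop
        if n < min_individuals:
            results.append(
                HWEResult(locus, label, math.nan, math.nan, settings,
                          testable=False, n_individuals=n,
                          note=f"not testable: only {n} individuals")
            )
            continue
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        results.append(
            hwe_exact_test(cnt, settings, seed=sub_seed, locus=locus, scope=label)
        )
    return results
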
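"""Population differentiation: pairwise F_ST and hierarchical AMOVA.

Both statistics come from the same variance-component machinery: genes (two
per typed diploid individual) are the units, the distance between two genes
is the 0/1 allele-identity mismatch, and sums of squared deviations are
partitioned hierarchically (among groups / among populations within groups /
within populations).  Variance components follow the standard moment
equations with unequal-sample-size coefficients; fixation indices are

    F_CT = s_a / s_T,   F_SC = s_b / (s_b + s_c),   F_ST = (s_a + s_b) / s_T

with ``s_T = s_a + s_b + s_c``.  Pairwise F_ST is the two-level special case
(the variance-component theta that the AMOVA framework yields for two
populations).  Components are summed over loci before forming ratios; a
genotype missing at a locus contributes nothing to that locus's components.
Negative components are reported as computed, never truncated.

Significance is by permutation: pairwise F_ST shuffles individuals between
the two populations (default 100 permutations); the AMOVA indices use the
scheme appropriate to each level (whole populations among groups for F_CT,
individuals among populations within groups for F_SC, individuals among all
populations for F_ST; default 10,000 permutations).  p-values use the
(b+1)/(B+1) estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_core import MISSING, GenotypeDataset
from .matrices import PairwiseMatrix

__all__ = [
    "AMOVAResult",
    "pairwise_fst",
    "fst_matrix",
    "fst_permutation_p",
    "global_fst",
    "amova_three_level",
]


# ---------------------------------------------------------------------------
# Gene-level bookkeeping
# ---------------------------------------------------------------------------

def _locus_genes(ds: GenotypeDataset) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Per locus: (individual index, allele index) per typed gene, and the
    number of distinct alleles."""
    out = []
    n = ds.n_individuals
    for j in range(ds.n_loci):
        calls = ds.alleles[:, j, :]
        typed = calls[:, 0] != MISSING
        vals = np.unique(calls[typed])
        ind = np.repeat(np.flatnonzero(typed), 2)
        al = np.searchsorted(vals, calls[typed].ravel())
        out.append((ind, al, len(vals)))
    return out


def _pop_counts(
    genes: tuple[np.ndarray, np.ndarray, int], pop_codes: np.ndarray, P: int
) -> np.ndarray:
    ind, al, A = genes
    if A == 0:
        return np.zeros((P, max(A, 1)))
    key = pop_codes[ind] * A + al
    return np.bincount(key, minlength=P * A).reshape(P, A).astype(float)


def _two_level_components(C: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """(SS_among, SS_within, df_a, df_c, sigma_a, sigma_c) from a pop x allele
    gene-count matrix."""
    n_p = C.sum(axis=1)
    active = n_p > 0
    C = C[active]
    n_p = n_p[active]
    N = n_p.sum()
    P = len(n_p)
    if P < 2 or N < 2:
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    Ct = C.sum(axis=0)
    ss_wp = 0.5 * (N - ((C**2).sum(axis=1) / n_p).sum())
    ss_tot = 0.5 * (N - (Ct**2).sum() / N)
    ss_ap = ss_tot - ss_wp
    df_c = N - P
    df_a = P - 1
    sigma_c = ss_wp / df_c if df_c > 0 else 0.0
    n_c = (N - (n_p**2).sum() / N) / df_a
    sigma_a = (ss_ap / df_a - sigma_c) / n_c if n_c > 0 else 0.0
    return ss_ap, ss_wp, df_a, df_c, sigma_a, sigma_c


def _three_level_components(
    C: np.ndarray, group_codes: np.ndarray, G: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """SS and variance components (a, b, c) for one locus, or None if the
    locus lacks two populations in two groups."""
    n_p = C.sum(axis=1)
    active = n_p > 0
    Ca = C[active]
    na = n_p[active]
    ga = group_codes[active]
    N = na.sum()
    A = C.shape[1]
    Cg = np.zeros((G, A))
    np.add.at(Cg, ga, Ca)
    n_g = Cg.sum(axis=1)
    g_active = n_g > 0
    P_eff = len(na)
    G_eff = int(g_active.sum())
    if G_eff < 2 or P_eff < 2:
        return None
    Ct = Ca.sum(axis=0)
    ss_wp = 0.5 * (N - ((Ca**2).sum(axis=1) / na).sum())
    ss_wg = 0.5 * (N - ((Cg[g_active] ** 2).sum(axis=1) / n_g[g_active]).sum())
    ss_tot = 0.5 * (N - (Ct**2).sum() / N)
    ss_b = ss_wg - ss_wp
    ss_a = ss_tot - ss_wg
    df_a = G_eff - 1
    df_b = P_eff - G_eff
    df_c = N - P_eff

    sigma_c = ss_wp / df_c if df_c > 0 else 0.0
    # unequal-sample-size coefficients
    s_g = np.zeros(G)
    np.add.at(s_g, ga, na.astype(float) ** 2)
    term1 = (s_g[g_active] / n_g[g_active]).sum()
    sum_np2 = (na.astype(float) ** 2).sum()
    sum_ng2 = (n_g[g_active] ** 2).sum()
    if df_b > 0:
        n1 = (N - term1) / df_b
        sigma_b = (ss_b / df_b - sigma_c) / n1 if n1 > 0 else 0.0
    else:
        sigma_b = 0.0
    n2 = (term1 - sum_np2 / N) / df_a
    n3 = (N - sum_ng2 / N) / df_a
    sigma_a = (ss_a / df_a - sigma_c - n2 * sigma_b) / n3 if n3 > 0 else 0.0
    return np.array([ss_a, ss_b, ss_wp]), np.array([sigma_a, sigma_b, sigma_c])


# ---------------------------------------------------------------------------
# Pairwise F_ST
# ---------------------------------------------------------------------------

def _theta_from_counts(per_locus_counts: list[np.ndarray]) -> float:
    """Multi-locus theta: components summed over loci before the ratio."""
    sa = sc = 0.0
    informative = False
    for C in per_locus_counts:
        n_p = C.sum(axis=1)
        if (n_p > 0).sum() < 2:
            continue
        informative = True
        _, _, _, _, s_a, s_c = _two_level_components(C)
        sa += s_a
        sc += s_c
    if not informative:
        return math.nan
    tot = sa + sc
    return sa / tot if tot > 0 else 0.0


def pairwise_fst(ds: GenotypeDataset, pop_a: str, pop_b: str) -> float:
    """Two-population variance-component theta over loci.

    May be slightly negative (estimator noise).  Loci untyped in either
    population are excluded; with no shared typed locus the value is NaN.
    """
    sub = ds.subset_populations([p for p in ds.populations if p in (pop_a, pop_b)])
    genes = _locus_genes(sub)
    counts = [_pop_counts(g, sub.pop_codes, 2) for g in genes]
    return _theta_from_counts(counts)


def global_fst(ds: GenotypeDataset) -> float:
    """Variance-component F_ST over all populations (two-level)."""
    genes = _locus_genes(ds)
    P = len(ds.populations)
    counts = [_pop_counts(g, ds.pop_codes, P) for g in genes]
    return _theta_from_counts(counts)


def fst_permutation_p(
    ds: GenotypeDataset,
    pop_a: str,
    pop_b: str,
    permutations: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """(theta, p) for one pair: individuals shuffled between the two pops."""
    sub = ds.subset_populations([p for p in ds.populations if p in (pop_a, pop_b)])
    genes = _locus_genes(sub)
    pc = sub.pop_codes
    obs = _theta_from_counts([_pop_counts(g, pc, 2) for g in genes])
    if math.isnan(obs):
        return obs, math.nan
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(pc)
        t = _theta_from_counts([_pop_counts(g, perm, 2) for g in genes])
        if not math.isnan(t) and t >= obs - 1e-12:
            hits += 1
    return obs, (hits + 1) / (permutations + 1)


def fst_matrix(
    ds: GenotypeDataset,
    permutations: int = 100,
    seed: int = 0,
) -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """All pairwise theta values plus one-sided permutation p-values.

    For each pair, individuals are shuffled between the two populations;
    ``p = (#{theta_perm >= theta_obs} + 1) / (B + 1)``.
    """
    pops = ds.populations
    k = len(pops)
    if k < 2:
        raise ValueError("need at least 2 populations")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(k * (k - 1) // 2))
    vals = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    np.fill_diagonal(pvals, 0.0)
    for i in range(k):
        for j in range(i + 1, k):
            rng = np.random.default_rng(next(children))
            sub = ds.subset_populations([pops[i], pops[j]])
            genes = _locus_genes(sub)
            pc = sub.pop_codes.copy()
            obs = _theta_from_counts([_pop_counts(g, pc, 2) for g in genes])
            vals[i, j] = vals[j, i] = obs
            if math.isnan(obs):
                continue
            hits = 0
            for _ in range(permutations):
                perm = rng.permutation(pc)
                t = _theta_from_counts([_pop_counts(g, perm, 2) for g in genes])
                if not math.isnan(t) and t >= obs - 1e-12:
                    hits += 1
            pvals[i, j] = pvals[j, i] = (hits + 1) / (permutations + 1)
    return PairwiseMatrix(tuple(pops), vals), PairwiseMatrix(tuple(pops), pvals)


# ---------------------------------------------------------------------------
# Hierarchical AMOVA
# ---------------------------------------------------------------------------

_LEVELS = (
    "Among groups (F_CT)",
    "Among populations within groups (F_SC)",
    "Within populations (F_ST)",
)


@dataclass(frozen=True)
class AMOVAResult:
    """Three-level variance decomposition with fixation indices and
    permutation p-values, in the standard report shape."""

    levels: tuple[str, str, str]
    df: tuple[int, int, int]
    SS: tuple[float, float, float]
    variance_components: tuple[float, float, float]
    percent_variation: tuple[float, float, float]
    f_ct: float
    f_sc: float
    f_st: float
    p_values: dict[str, float]
    permutations: int
    n_individuals: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, df_, ss, vc, pct, p in zip(
            self.levels,
            self.df,
            self.SS,
            self.variance_components,
            self.percent_variation,
            [self.p_values.get(k, math.nan) for k in ("F_CT", "F_SC", "F_ST")],
        ):
            rows.append(
                {"variance_component": name, "df": df_, "SS": ss,
                 "variance": vc, "variation_pct": pct, "p_value": p}
            )
        rows.append(
            {"variance_component": "Total", "df": sum(self.df),
             "SS": sum(self.SS), "variance": sum(self.variance_components),
             "variation_pct": 100.0 if not math.isnan(self.f_st) else math.nan,
             "p_value": math.nan}
        )
        return pd.DataFrame(rows)


def _amova_stat(
    genes: list[tuple[np.ndarray, np.ndarray, int]],
    pop_codes: np.ndarray,
    group_codes: np.ndarray,
    P: int,
    G: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Summed SS and variance components over loci for one configuration."""
    SS = np.zeros(3)
    sig = np.zeros(3)
    for g in genes:
        C = _pop_counts(g, pop_codes, P)
        res = _three_level_components(C, group_codes, G)
        if res is None:
            continue
        ss, s = res
        SS += ss
        sig += s
    return SS, sig


def _indices(sig: np.ndarray) -> tuple[float, float, float]:
    sa, sb, sc = sig
    tot = sa + sb + sc
    if tot <= 0:
        return math.nan, math.nan, math.nan
    f_ct = sa / tot
    if sb + sc > 0:
        f_sc = sb / (sb + sc)
    else:
        # no variation below the group level: F_SC degenerates to 0
        f_sc = 0.0 if abs(sb) < 1e-15 else math.nan
    f_st = (sa + sb) / tot
    return f_ct, f_sc, f_st


def amova_three_level(
    ds: GenotypeDataset,
    grouping: Mapping[str, str] | None = None,
    permutations: int = 10_000,
    seed: int = 0,
    test_indices: Sequence[str] = ("F_CT", "F_SC", "F_ST"),
) -> AMOVAResult:
    """Three-level AMOVA: groups (watersheds) / populations / individuals' genes.

    ``grouping`` maps population id to group label; by default it is taken
    from the sites' ``group_id``.  Reported df are the complete-data partition
    (G-1, P-G, 2N-P), so they sum to 2N-1; SS and variance components use
    locus-wise exclusion of missing genotypes and are summed over loci.
    """
    pops = ds.populations
    if grouping is None:
        grouping = {p: ds.site(p).group_id for p in pops}
    missing = [p for p in pops if not grouping.get(p)]
    if missing:
        raise ValueError(f"populations without group label: {missing}")
    groups: list[str] = []
    for p in pops:
        if grouping[p] not in groups:
            groups.append(grouping[p])
    G, P = len(groups), len(pops)
    if G < 2:
        raise ValueError("hierarchical AMOVA needs at least 2 groups "
                         "(a single group containing all populations leaves "
                         "F_CT undefined)")
    gidx = {g: i for i, g in enumerate(groups)}
    group_codes = np.array([gidx[grouping[p]] for p in pops])

    genes = _locus_genes(ds)
    SS, sig = _amova_stat(genes, ds.pop_codes, group_codes, P, G)
    f_ct, f_sc, f_st = _indices(sig)

    n = ds.n_individuals
    df = (G - 1, P - G, 2 * n - P)
    tot = sig.sum()
    pct = tuple(100.0 * s / tot if tot > 0 else math.nan for s in sig)

    rng_ct, rng_sc, rng_st = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)
    )
    p_values: dict[str, float] = {}
    if permutations > 0 and "F_CT" in test_indices and not math.isnan(f_ct):
        # F_CT: permute whole populations among groups
        hits = 0
        for _ in range(permutations):
            gp = rng_ct.permutation(group_codes)
            _, s = _amova_stat(genes, ds.pop_codes, gp, P, G)
            stat = _indices(s)[0]
            if not math.isnan(stat) and stat >= f_ct - 1e-12:
                hits += 1
        p_values["F_CT"] = (hits + 1) / (permutations + 1)

    if permutations > 0 and "F_SC" in test_indices and not math.isnan(f_sc):
        # F_SC: permute individuals among populations within groups
        ind_groups = group_codes[ds.pop_codes]
        within_idx = [np.flatnonzero(ind_groups == gi) for gi in range(G)]
        hits = 0
        for _ in range(permutations):
            pc = ds.pop_codes.copy()
            for idx in within_idx:
                if len(idx) > 1:
                    pc[idx] = pc[idx[rng_sc.permutation(len(idx))]]
            _, s = _amova_stat(genes, pc, group_codes, P, G)
            stat = _indices(s)[1]
            if not math.isnan(stat) and stat >= f_sc - 1e-12:
                hits += 1
        p_values["F_SC"] = (hits + 1) / (permutations + 1)

    if permutations > 0 and "F_ST" in test_indices and not math.isnan(f_st):
        # F_ST: permute individuals among populations across the whole sample
        hits = 0
        for _ in range(permutations):
            pc = rng_st.permutation(ds.pop_codes)
            _, s = _amova_stat(genes, pc, group_codes, P, G)
            stat = _indices(s)[2]
            if not math.isnan(stat) and stat >= f_st - 1e-12:
                hits += 1
        p_values["F_ST"] = (hits + 1) / (permutations + 1)

    return AMOVAResult(
        levels=_LEVELS,
        df=df,
        SS=tuple(SS),
        variance_components=tuple(sig),
        percent_variation=pct,
        f_ct=f_ct,
        f_sc=f_sc,
        f_st=f_st,
        p_values=p_values,
        permutations=permutations,
        n_individuals=n,
    )
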
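"""Pairwise theta and hierarchical AMOVA against brute-force oracles.

The oracle evaluates sums of squares directly from the pairwise 0/1
allele-mismatch matrix among genes (``SSD(unit) = (1/n) sum_{i<j} d_ij``)
and solves the moment equations with explicitly computed unequal-sample-size
coefficients — an independent path from the production implementation's
count-matrix algebra.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from popcompare.differentiation import (
    amova_three_level,
    fst_matrix,
    fst_permutation_p,
    global_fst,
    pairwise_fst,
)
from popcompare.genotype_core import MISSING, GenotypeDataset, PopulationSite
from popcompare.synthetic_data import SimulationConfig, simulate

from conftest import make_dataset


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _gene_list(ds: GenotypeDataset, locus_idx: int):
    """(allele, pop, group) per typed gene."""
    genes = []
    groups = {p: ds.site(p).group_id for p in ds.populations}
    for i in range(ds.n_individuals):
        a, b = ds.alleles[i, locus_idx]
        if a == MISSING:
            continue
        pop = ds.individual_pops[i]
        genes.append((int(a), pop, groups[pop]))
        genes.append((int(b), pop, groups[pop]))
    return genes


def _ssd(genes) -> float:
    n = len(genes)
    if n < 2:
        return 0.0
    total = sum(
        1 for g1, g2 in itertools.combinations(genes, 2) if g1[0] != g2[0]
    )
    return total / n


def oracle_amova(ds: GenotypeDataset):
    """(SS_a, SS_b, SS_c, sigma_a, sigma_b, sigma_c) summed over loci."""
    SS = np.zeros(3)
    sig = np.zeros(3)
    for j in range(ds.n_loci):
        genes = _gene_list(ds, j)
        pops = sorted({g[1] for g in genes})
        grps = sorted({g[2] for g in genes})
        N, P, G = len(genes), len(pops), len(grps)
        if P < 2 or G < 2:
            continue
        ssd_t = _ssd(genes)
        ssd_wp = sum(_ssd([g for g in genes if g[1] == p]) for p in pops)
        ssd_wg = sum(_ssd([g for g in genes if g[2] == w]) for w in grps)
        ss_a, ss_b, ss_c = ssd_t - ssd_wg, ssd_wg - ssd_wp, ssd_wp
        SS += (ss_a, ss_b, ss_c)

        n_p = {p: sum(1 for g in genes if g[1] == p) for p in pops}
        n_g = {w: sum(1 for g in genes if g[2] == w) for w in grps}
        pg = {p: next(g[2] for g in genes if g[1] == p) for p in pops}
        df_a, df_b, df_c = G - 1, P - G, N - P
        s_c = ss_c / df_c if df_c else 0.0
        term1 = sum(
            sum(n_p[p] ** 2 for p in pops if pg[p] == w) / n_g[w] for w in grps
        )
        if df_b:
            n1 = (N - term1) / df_b
            s_b = (ss_b / df_b - s_c) / n1
        else:
            s_b = 0.0
        n2 = (term1 - sum(v**2 for v in n_p.values()) / N) / df_a
        n3 = (N - sum(v**2 for v in n_g.values()) / N) / df_a
        s_a = (ss_a / df_a - s_c - n2 * s_b) / n3
        sig += (s_a, s_b, s_c)
    return SS, sig


def oracle_two_level_theta(ds: GenotypeDataset) -> float:
    sa = sc = 0.0
    for j in range(ds.n_loci):
        genes = _gene_list(ds, j)
        pops = sorted({g[1] for g in genes})
        N, P = len(genes), len(pops)
        if P < 2:
            continue
        ssd_t = _ssd(genes)
        ssd_wp = sum(_ssd([g for g in genes if g[1] == p]) for p in pops)
        ss_a, ss_c = ssd_t - ssd_wp, ssd_wp
        n_p = {p: sum(1 for g in genes if g[1] == p) for p in pops}
        s_c = ss_c / (N - P) if N > P else 0.0
        n_c = (N - sum(v**2 for v in n_p.values()) / N) / (P - 1)
        s_a = (ss_a / (P - 1) - s_c) / n_c
        sa += s_a
        sc += s_c
    return sa / (sa + sc)


def _grouped_sites(pop_to_group: dict[str, str]):
    return [
        PopulationSite(p, 0.0, 0.0, g) for p, g in pop_to_group.items()
    ]


# ---------------------------------------------------------------------------
# Pairwise F_ST
# ---------------------------------------------------------------------------

class TestPairwiseFst:
    def test_complete_fixation_gives_one(self, fixed_difference):
        assert pairwise_fst(fixed_difference, "p1", "p2") == pytest.approx(1.0)

    def test_cloned_population_is_near_zero(self):
        rng = np.random.default_rng(7)
        genos = [
            [tuple(sorted(rng.integers(1, 5, 2))) for _ in range(5)]
            for _ in range(30)
        ]
        ds = make_dataset({"a": genos[:15], "b": genos[15:]})
        theta = pairwise_fst(ds, "a", "b")
        assert theta <= 0.05 and abs(theta) < 0.05

    def test_hand_instance_matches_oracle(self, two_pop_one_locus):
        theta = pairwise_fst(two_pop_one_locus, "p1", "p2")
        assert theta == pytest.approx(oracle_two_level_theta(two_pop_one_locus),
                                      abs=1e-12)

    def test_untyped_locus_excluded(self):
        ds = make_dataset(
            {"a": [[(1, 1), (0, 0)]] * 3, "b": [[(2, 2), (5, 6)]] * 3}
        )
        # locus 2 typed only in b: theta driven entirely by locus 1
        assert pairwise_fst(ds, "a", "b") == pytest.approx(1.0)

    def test_no_shared_locus_is_na(self):
        ds = make_dataset({"a": [[(1, 1), (0, 0)]], "b": [[(0, 0), (2, 2)]]})
        assert math.isnan(pairwise_fst(ds, "a", "b"))


class TestFstMatrix:
    def test_symmetry_and_label_consistency(self):
        cfg = SimulationConfig(demes=3, deme_size=20, migration=0.05, loci=4,
                               generations=50, sample_sizes=8,
                               founder_alleles=4, seed=3)
        ds = simulate(cfg)
        m, p = fst_matrix(ds, permutations=19, seed=0)
        assert np.allclose(m.values, m.values.T)
        assert m.labels == tuple(ds.populations)
        re = m.reorder(list(reversed(m.labels)))
        for a, b in m.pairs():
            assert re[a, b] == m[a, b]

    def test_fixed_difference_pair_minimal_p(self, fixed_difference):
        B = 99
        _, pvals = fst_matrix(fixed_difference, permutations=B, seed=1)
        # no permutation exceeds theta=1; ties occur only when a permutation
        # recreates the two-sided split exactly (prob 2/C(6,3) = 0.1 at n=3+3)
        assert 1 / (B + 1) <= pvals["p1", "p2"] <= 0.3

    def test_matches_single_pair_helper(self, two_pop_one_locus):
        m, _ = fst_matrix(two_pop_one_locus, permutations=0, seed=0)
        theta, _ = fst_permutation_p(two_pop_one_locus, "p1", "p2",
                                     permutations=0, seed=0)
        assert m["p1", "p2"] == pytest.approx(theta)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

class TestAmova:
    def test_perfect_group_structure(self):
        ds = make_dataset(
            {
                "a1": [[(1, 1)]] * 3, "a2": [[(1, 1)]] * 3,
                "b1": [[(2, 2)]] * 3, "b2": [[(2, 2)]] * 3,
            },
            sites=_grouped_sites({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}),
        )
        res = amova_three_level(ds, permutations=0)
        assert res.f_ct == pytest.approx(1.0)
        assert res.f_sc == pytest.approx(0.0, abs=1e-12)
        assert res.variance_components[2] == pytest.approx(0.0)

    def test_monomorphic_dataset_degenerates(self):
        ds = make_dataset(
            {"a": [[(1, 1)]] * 3, "b": [[(1, 1)]] * 3,
             "c": [[(1, 1)]] * 3, "d": [[(1, 1)]] * 3},
            sites=_grouped_sites({"a": "A", "b": "A", "c": "B", "d": "B"}),
        )
        res = amova_three_level(ds, permutations=0)
        assert res.SS == (0.0, 0.0, 0.0)
        assert math.isnan(res.f_st)

    def test_single_group_errors(self):
        ds = make_dataset(
            {"a": [[(1, 2)]] * 3, "b": [[(1, 1)]] * 3},
            sites=_grouped_sites({"a": "W", "b": "W"}),
        )
        with pytest.raises(ValueError, match="at least 2 groups"):
            amova_three_level(ds, permutations=0)

    def test_matches_quadratic_form_oracle_on_fixtures(self):
        """SS and variance components equal direct pairwise-mismatch evaluation
        on every fixture with <= 12 individuals."""
        fixtures = []
        # 3 groups x 2 pops x 2 diploid individuals x 2 loci, fixed genotypes
        fixtures.append(
            make_dataset(
                {
                    "p1": [[(1, 2), (5, 5)], [(1, 1), (5, 6)]],
                    "p2": [[(2, 2), (6, 6)], [(1, 2), (5, 6)]],
                    "p3": [[(3, 3), (7, 7)], [(3, 4), (7, 8)]],
                    "p4": [[(4, 4), (8, 8)], [(3, 3), (7, 7)]],
                    "p5": [[(1, 4), (5, 8)], [(2, 3), (6, 7)]],
                    "p6": [[(4, 4), (8, 8)], [(2, 2), (6, 6)]],
                },
                sites=_grouped_sites(
                    {"p1": "A", "p2": "A", "p3": "B", "p4": "B",
                     "p5": "C", "p6": "C"}
                ),
            )
        )
        # unbalanced sizes and missing data
        fixtures.append(
            make_dataset(
                {
                    "x": [[(1, 1), (0, 0)], [(1, 2), (9, 9)], [(2, 2), (9, 10)]],
                    "y": [[(1, 2), (10, 10)]],
                    "z": [[(2, 2), (9, 10)], [(2, 2), (10, 10)],
                          [(1, 2), (0, 0)], [(1, 1), (9, 9)]],
                },
                sites=_grouped_sites({"x": "N", "y": "N", "z": "S"}),
            )
        )
        # random small instance
        rng = np.random.default_rng(11)
        genos = {
            p: [[tuple(sorted(rng.integers(1, 4, 2))) for _ in range(2)]
                for _ in range(3)]
            for p in ("q1", "q2", "q3", "q4")
        }
        fixtures.append(
            make_dataset(
                genos,
                sites=_grouped_sites({"q1": "G1", "q2": "G1",
                                      "q3": "G2", "q4": "G2"}),
            )
        )
        for ds in fixtures:
            assert ds.n_individuals <= 12
            res = amova_three_level(ds, permutations=0)
            SS, sig = oracle_amova(ds)
            assert np.allclose(res.SS, SS, atol=1e-10), ds
            assert np.allclose(res.variance_components, sig, atol=1e-10), ds

    def test_df_and_percent_conservation(self):
        cfg = SimulationConfig(demes=4, deme_size=20, migration=0.02, loci=5,
                               generations=80, sample_sizes=[6, 9, 5, 8],
                               founder_alleles=5, seed=9,
                               group_map={0: "A", 1: "A", 2: "B", 3: "B"})
        ds = simulate(cfg)
        res = amova_three_level(ds, permutations=0)
        assert sum(res.df) == 2 * ds.n_individuals - 1
        assert sum(res.percent_variation) == pytest.approx(100.0, abs=1e-9)

    def test_two_level_consistency(self):
        """Every population its own group: AMOVA F_ST equals the global
        variance-component F_ST."""
        cfg = SimulationConfig(demes=4, deme_size=20, migration=0.02, loci=5,
                               generations=80, sample_sizes=10,
                               founder_alleles=5, seed=17)
        ds = simulate(cfg)
        grouping = {p: p for p in ds.populations}
        res = amova_three_level(ds, grouping, permutations=0)
        assert res.f_st == pytest.approx(global_fst(ds), abs=1e-12)

    def test_report_shape(self):
        ds = make_dataset(
            {"a": [[(1, 2)]] * 3, "b": [[(1, 1)]] * 3,
             "c": [[(2, 2)]] * 3, "d": [[(1, 2)]] * 3},
            sites=_grouped_sites({"a": "A", "b": "A", "c": "B", "d": "B"}),
        )
        res = amova_three_level(ds, permutations=49, seed=2)
        df = res.to_dataframe()
        assert list(df["variance_component"])[-1] == "Total"
        assert df["df"].iloc[-1] == 2 * ds.n_individuals - 1
        assert set(res.p_values) == {"F_CT", "F_SC", "F_ST"}
        assert all(0 < p <= 1 for p in res.p_values.values())
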
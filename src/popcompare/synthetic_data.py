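"""Forward-time stepping-stone simulator for microsatellite genotype data,
plus a matching toy landscape generator.

The genotype generator is a discrete-generation Wright–Fisher metapopulation:
``demes`` demes of constant diploid size arranged in a 1-D chain, 2-D grid or
island (all-to-all) layout.  Each offspring draws two parents — each parent
from a neighbouring deme with probability ``migration`` per neighbour
(gametic migration), otherwise from home — inherits one allele per parent per
locus (free recombination across loci), and each transmitted allele mutates
by ±1 repeat with probability ``mutation_rate`` (stepwise mutation model,
reflecting at allele value 1).  After ``generations`` of burn-in,
``sample_sizes`` individuals per deme are drawn without replacement and
per-genotype dropout is applied.  Everything is deterministic under the
configured seed.

Founder state: all genes start from ``founder_alleles`` equally spaced repeat
values (default 1, i.e. a monomorphic founder — with no mutation the dataset
stays monomorphic).  Presets use a diverse founder pool so that realistic
standing variation exists within a short burn-in.

Three scenario presets mirror the qualitative patterns the analysis is meant
to distinguish: ``panmixia`` (one deme sampled into pseudo-populations),
``strong_IBD`` (chain with nearest-neighbour migration), and
``hierarchical_watersheds`` (chain whose between-group migration is reduced
tenfold relative to within-group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genotype_core import (
    MISSING,
    GenotypeDataset,
    PopulationSite,
    write_genepop,
    write_site_metadata,
)
from .landscape import (
    CostRaster,
    HabitatRule,
    build_cost_raster,
    write_ascii_grid,
    write_feature_layers,
)

__all__ = [
    "SimulationConfig",
    "ScenarioPreset",
    "simulate",
    "simulate_landscape",
    "expected_fst_island",
    "preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated study.

    ``migration`` is the per-generation probability that a gamete comes from
    one specific neighbouring deme, so the total emigration probability is
    ``migration x n_neighbours`` (must stay <= 1).  ``generations`` of None
    means the default burn-in of 10 x deme_size.  ``group_map`` assigns demes
    (0-based index) to named groups; migration between demes in different
    groups is multiplied by ``between_group_factor``.
    """

    demes: int = 8
    layout: str = "chain"  # chain | grid | island
    deme_size: int = 50
    migration: float = 0.01
    loci: int = 10
    mutation_rate: float = 5e-4
    generations: int | None = None
    sample_sizes: int | Sequence[int] = 20
    missing_rate: float = 0.0
    seed: int = 0
    founder_alleles: int = 1
    grid_shape: tuple[int, int] | None = None
    pseudo_subpopulations: int = 1
    group_map: Mapping[int, str] | None = None
    between_group_factor: float = 1.0
    # landscape emulation
    spacing_m: float = 50_000.0
    origin_m: tuple[float, float] = (350_000.0, 7_400_000.0)
    climate_gradients: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            # base value, change per deme step, noise sd
            "precip_mm": (400.0, 40.0, 15.0),
            "isothermality": (55.0, -1.5, 0.8),
        }
    )

    def __post_init__(self) -> None:
        if self.deme_size < 2:
            raise ValueError("deme_size must be >= 2")
        if not 0 <= self.migration <= 0.5:
            raise ValueError("per-neighbour migration must be in [0, 0.5]")
        if not 0 <= self.mutation_rate <= 0.1:
            raise ValueError("mutation rate must be in [0, 0.1]")
        if self.layout not in ("chain", "grid", "island"):
            raise ValueError(f"unknown layout {self.layout!r}")
        nb = _neighbours(self)
        max_out = max(
            (sum(r for _, r in nbs) for nbs in nb.values()), default=0.0
        )
        if max_out > 1:
            raise ValueError("total outgoing migration exceeds 1 for some deme")

    @property
    def burn_in(self) -> int:
        return self.generations if self.generations is not None else 10 * self.deme_size

    def per_deme_samples(self) -> list[int]:
        if isinstance(self.sample_sizes, int):
            return [self.sample_sizes] * self.demes
        sizes = list(self.sample_sizes)
        if len(sizes) != self.demes:
            raise ValueError("sample_sizes length must equal deme count")
        return sizes


def _deme_positions(config: SimulationConfig) -> np.ndarray:
    """Deme lattice coordinates (in deme steps)."""
    if config.layout == "grid":
        if config.grid_shape is None:
            side = int(math.sqrt(config.demes))
            if side * side != config.demes:
                raise ValueError("grid layout needs a square deme count or grid_shape")
            shape = (side, side)
        else:
            shape = config.grid_shape
            if shape[0] * shape[1] != config.demes:
                raise ValueError("grid_shape inconsistent with deme count")
        return np.array([(i % shape[1], i // shape[1]) for i in range(config.demes)],
                        dtype=float)
    return np.array([(0.0, float(i)) for i in range(config.demes)])


def _neighbours(config: SimulationConfig) -> dict[int, list[tuple[int, float]]]:
    """Per deme: (neighbour index, per-gamete migration rate)."""
    d = config.demes
    m = config.migration
    groups = config.group_map or {}
    factor = config.between_group_factor

    def rate(a: int, b: int) -> float:
        if groups and groups.get(a) != groups.get(b):
            return m * factor
        return m

    out: dict[int, list[tuple[int, float]]] = {i: [] for i in range(d)}
    if config.layout == "island":
        for i in range(d):
            out[i] = [(j, rate(i, j)) for j in range(d) if j != i]
    elif config.layout == "chain":
        for i in range(d):
            for j in (i - 1, i + 1):
                if 0 <= j < d:
                    out[i].append((j, rate(i, j)))
    else:  # grid
        pos = _deme_positions(config)
        for i in range(d):
            for j in range(d):
                if i != j and abs(pos[i] - pos[j]).sum() == 1:
                    out[i].append((j, rate(i, j)))
    return out


# ---------------------------------------------------------------------------
# Core simulation
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig, seed: int | None = None) -> GenotypeDataset:
    """Run the forward Wright–Fisher simulation and sample a genotype dataset."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    D, N, L = config.demes, config.deme_size, config.loci
    samples = config.per_deme_samples()
    for d, s in enumerate(samples):
        if s > N:
            raise ValueError(f"sample size {s} exceeds deme size {N} (deme {d})")

    # founder pool: equally spaced repeat values centred near 10
    k = max(1, config.founder_alleles)
    founders = np.arange(10, 10 + k)
    pop = rng.choice(founders, size=(D, N, L, 2))

    nbs = _neighbours(config)
    nb_idx = [np.array([j for j, _ in nbs[d]], dtype=int) for d in range(D)]
    nb_cum = []
    for d in range(D):
        rates = np.array([r for _, r in nbs[d]])
        nb_cum.append(np.concatenate([[0.0], np.cumsum(rates)]))

    mu = config.mutation_rate
    for _ in range(config.burn_in):
        new = np.empty_like(pop)
        for d in range(D):
            src = np.full((N, 2), d, dtype=int)
            if len(nb_idx[d]):
                u = rng.random((N, 2))
                total = nb_cum[d][-1]
                migrant = u < total
                if migrant.any():
                    which = np.searchsorted(nb_cum[d], u[migrant], side="right") - 1
                    src[migrant] = nb_idx[d][which]
            par = rng.integers(0, N, (N, 2))
            coin = rng.integers(0, 2, (N, 2, L))
            gam = pop[src, par]  # (N, 2, L, 2)
            new[d] = np.take_along_axis(
                gam, coin[..., None], axis=-1
            )[..., 0].transpose(0, 2, 1)
        if mu > 0:
            mask = rng.random(new.shape) < mu
            if mask.any():
                steps = rng.integers(0, 2, new.shape) * 2 - 1
                mutated = new + np.where(mask, steps, 0)
                mutated[mutated < 1] = 2  # reflect at repeat count 1
                new = mutated
        pop = new

    # sampling
    loci_names = [f"L{j + 1:02d}" for j in range(L)]
    rows, ids, pops_out = [], [], []
    pseudo = max(1, config.pseudo_subpopulations)
    if pseudo > 1 and D != 1:
        raise ValueError("pseudo-subpopulations require a single deme")
    for d in range(D):
        chosen = rng.choice(N, size=samples[d], replace=False)
        geno = pop[d, chosen].copy()  # (s, L, 2)
        if config.missing_rate > 0:
            drop = rng.random((samples[d], L)) < config.missing_rate
            geno[drop] = MISSING
        if pseudo > 1:
            share = samples[d] // pseudo
            for q in range(pseudo):
                block = geno[q * share: (q + 1) * share] if q < pseudo - 1 else geno[q * share:]
                name = f"deme{q + 1}"
                for r, g in enumerate(block):
                    rows.append(g)
                    ids.append(f"{name}_{r + 1}")
                    pops_out.append(name)
        else:
            name = f"deme{d + 1}"
            for r, g in enumerate(geno):
                rows.append(g)
                ids.append(f"{name}_{r + 1}")
                pops_out.append(name)
    alleles = np.stack(rows) if rows else np.empty((0, L, 2), dtype=np.int64)
    sites = _make_sites(config, rng)
    return GenotypeDataset(loci_names, alleles, ids, pops_out, sites)


def _make_sites(config: SimulationConfig, rng: np.random.Generator) -> list[PopulationSite]:
    n_sites = config.pseudo_subpopulations if config.pseudo_subpopulations > 1 else config.demes
    if config.pseudo_subpopulations > 1:
        pos = np.array([(0.0, float(i)) for i in range(n_sites)])
    else:
        pos = _deme_positions(config)
    groups = config.group_map or {}
    x0, y0 = config.origin_m
    sites = []
    for i in range(n_sites):
        climate = {}
        for var, (base, slope, sd) in config.climate_gradients.items():
            val = base + slope * pos[i, 1] + (rng.normal(0, sd) if sd > 0 else 0.0)
            climate[var] = max(0.0, val)
        sites.append(
            PopulationSite(
                id=f"deme{i + 1}",
                easting=x0 + pos[i, 0] * config.spacing_m,
                northing=y0 + pos[i, 1] * config.spacing_m,
                group_id=str(groups.get(i, "")),
                climate=climate,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Landscape emulation
# ---------------------------------------------------------------------------

def simulate_landscape(
    config: SimulationConfig,
    seed: int | None = None,
    buffer_km: float = 10.0,
    outside_penalty: float = 100.0,
    resolution: float | None = None,
) -> tuple[list[PopulationSite], CostRaster, dict[str, list[tuple[float, float]]]]:
    """Sites with UTM-like coordinates and climate scalars, a coastline
    feature layer running past the demes, and the matching cost raster.

    Sites sit a few kilometers inland of a north–south coastline, so the
    coastal buffer forms a corridor connecting all demes; climate scalars
    follow the configured linear gradient plus noise, making climate
    dissimilarity correlate with distance as the landscape models assume.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sites = _make_sites(config, rng)
    xs = [s.easting for s in sites]
    ys = [s.northing for s in sites]
    margin = 2.5 * buffer_km * 1000.0
    coast_x = min(xs) - buffer_km * 500.0  # coastline ~ half a buffer west
    features = {
        "coastline": [
            (coast_x, min(ys) - margin),
            (coast_x, max(ys) + margin),
        ]
    }
    rule = HabitatRule(
        feature_layers=features, buffer_km=buffer_km, outside_penalty=outside_penalty
    )
    res = resolution if resolution is not None else buffer_km * 1000.0 / 2
    extent = (
        min(xs) - margin, min(ys) - margin, max(xs) + margin, max(ys) + margin
    )
    raster = build_cost_raster(rule, extent, res)
    for s in sites:
        if not raster.contains(s.easting, s.northing):
            raise AssertionError(f"site {s.id} outside generated raster")
    return sites, raster, features


# ---------------------------------------------------------------------------
# Island-model expectation (coarse oracle)
# ---------------------------------------------------------------------------

def expected_fst_island(
    deme_size: int, migration_total: float, mutation_rate: float, demes: int
) -> float:
    """Finite-island equilibrium expectation
    ``1 / (1 + 4N(m + mu) (d/(d-1))^2)`` — a coarse oracle band only."""
    if demes < 2:
        raise ValueError("island expectation needs at least 2 demes")
    alpha = (demes / (demes - 1)) ** 2
    denom = 1.0 + 4.0 * deme_size * (migration_total + mutation_rate) * alpha
    return 1.0 / denom


def expected_fst_for_config(config: SimulationConfig) -> float:
    if config.layout != "island":
        raise ValueError("closed-form expectation applies to the island layout")
    m_total = config.migration * (config.demes - 1)
    return expected_fst_island(
        config.deme_size, m_total, config.mutation_rate, config.demes
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    config: SimulationConfig


PRESET_NAMES = ("panmixia", "strong_IBD", "hierarchical_watersheds")


def preset(name: str, seed: int = 0) -> ScenarioPreset:
    """Bind one of the named scenario presets to a seed.

    * ``panmixia`` — one deme of 160, sampled into 4 pseudo-populations of 20;
      no spatial signal of any kind.
    * ``strong_IBD`` — 8 demes in a chain, nearest-neighbour migration 0.01,
      deme size 50, mu = 5e-4, 10 loci, 20 sampled per deme.
    * ``hierarchical_watersheds`` — the same chain split into 4 groups of 2
      demes with between-group migration reduced tenfold.
    """
    if name == "panmixia":
        cfg = SimulationConfig(
            demes=1, layout="chain", deme_size=160, migration=0.0, loci=10,
            mutation_rate=5e-4, sample_sizes=80, pseudo_subpopulations=4,
            founder_alleles=8, generations=200, seed=seed,
        )
    elif name == "strong_IBD":
        cfg = SimulationConfig(
            demes=8, layout="chain", deme_size=50, migration=0.01, loci=10,
            mutation_rate=5e-4, sample_sizes=20, founder_alleles=8, seed=seed,
        )
    elif name == "hierarchical_watersheds":
        cfg = SimulationConfig(
            demes=8, layout="chain", deme_size=50, migration=0.05, loci=10,
            mutation_rate=5e-4, sample_sizes=20, founder_alleles=8, seed=seed,
            group_map={i: f"W{i // 2 + 1}" for i in range(8)},
            between_group_factor=0.1,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return ScenarioPreset(name=name, config=cfg)


def write_bundle(
    config: SimulationConfig, outdir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Simulate and write the full input bundle in the pipeline's formats:
    Genepop genotypes, site-metadata table, ESRI ASCII cost raster and
    feature-layer file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate(config, seed)
    sites, raster, features = simulate_landscape(config, seed)
    ds = ds.with_sites(sites[: len(ds.sites)])
    paths = {
        "genotypes": outdir / "genotypes.gen",
        "sites": outdir / "sites.csv",
        "raster": outdir / "cost.asc",
        "features": outdir / "features.csv",
    }
    write_genepop(ds, paths["genotypes"])
    write_site_metadata(ds.sites, paths["sites"])
    write_ascii_grid(raster, paths["raster"])
    write_feature_layers(features, paths["features"])
    return paths
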
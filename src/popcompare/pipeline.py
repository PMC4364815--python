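"""End-to-end orchestration: diversity -> HWE -> F_ST -> AMOVA -> Euclidean
IBD -> landscape IBD, with fail-fast input validation, per-stage toggles,
structured warnings, and deterministic seeding.

Stage order follows the analysis workflow: the simple Euclidean
isolation-by-distance model is assessed before the landscape-based models,
which rest on more assumptions.  All randomness flows from the single run
seed through per-stage derived streams, so re-running a config reproduces
every number exactly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import ChainSettings, diversity_table, hwe_test_dataset, sequential_bonferroni
from .differentiation import amova_three_level, fst_matrix
from .genotype_core import (
    GenotypeDataset,
    read_genepop,
    read_site_metadata,
    read_structure_table,
)
from .landscape import (
    bray_curtis_matrix,
    build_cost_raster,
    euclidean_matrix,
    HabitatRule,
    least_cost_matrix,
    read_ascii_grid,
    read_feature_layers,
)
from .matrices import PairwiseMatrix
from .mrmpa import MatrixRegressionProblem, model_average, pair_weight_matrix

__all__ = ["RunConfig", "RunReport", "run", "compare_species", "load_config"]

_STAGES = ("diversity", "hwe", "fst", "amova", "ibd_euclidean", "ibd_landscape")


@dataclass
class RunConfig:
    """Declarative configuration of one cohort analysis."""

    genotypes: str
    sites: str
    output_dir: str
    cohort: str = ""
    genotype_format: str = "genepop"  # genepop | structure
    raster: str | None = None
    features: str | None = None
    buffer_km: float = 10.0
    outside_penalty: float = 100.0
    resolution: float = 5000.0
    stages: Sequence[str] = _STAGES
    rarefaction_genes: int = 4
    hwe_dememorization: int = 10_000
    hwe_batches: int = 1_000
    hwe_iterations: int = 10_000
    alpha: float = 0.05
    fst_permutations: int = 100
    amova_permutations: int = 10_000
    mrmpa_permutations: int = 10_000
    weight_rule: str = "sum"
    climate_variables: Sequence[str] = ("precip_mm", "isothermality")
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            problems.append(f"unknown stages {unknown}; valid: {_STAGES}")
        for name, p in (("genotypes", self.genotypes), ("sites", self.sites)):
            if not Path(p).exists():
                problems.append(f"{name} file not found: {p}")
        if "ibd_landscape" in self.stages:
            if self.raster is None and self.features is None:
                problems.append(
                    "ibd_landscape enabled but neither a cost raster nor a "
                    "feature layer file was supplied"
                )
            for p in (self.raster, self.features):
                if p is not None and not Path(p).exists():
                    problems.append(f"landscape input not found: {p}")
        return problems


@dataclass
class RunReport:
    config: dict[str, Any]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict[str, Any] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
        (outdir / "summary.json").write_text(
            json.dumps(self.summary, indent=2, sort_keys=True, default=str) + "\n"
        )


def load_config(path: str | Path, **overrides: Any) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def _load_dataset(config: RunConfig) -> GenotypeDataset:
    if config.genotype_format == "genepop":
        ds = read_genepop(config.genotypes)
    elif config.genotype_format == "structure":
        ds = read_structure_table(config.genotypes)
    else:
        raise ValueError(f"unknown genotype format {config.genotype_format!r}")
    sites = read_site_metadata(config.sites)
    return ds.with_sites(sites)


def run(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order; fail fast on unresolvable inputs."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid run configuration:\n- " + "\n- ".join(problems))

    report = RunReport(config=dict(vars(config)))
    caught: list[str] = []
    ss = np.random.SeedSequence(config.seed)
    stage_seed = {
        s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(_STAGES, ss.spawn(len(_STAGES)))
    }

    with warnings.catch_warnings(record=True) as wlog:
        warnings.simplefilter("always")
        ds = _load_dataset(config)
        report.summary.update(
            version=__version__,
            seed=config.seed,
            n_individuals=ds.n_individuals,
            n_loci=ds.n_loci,
            loci=ds.loci,
            populations=ds.populations,
            sample_sizes=ds.sample_sizes(),
        )

        fst = None
        if "diversity" in config.stages:
            report.tables["diversity"] = diversity_table(
                ds, config.rarefaction_genes, cohort=config.cohort
            )
        if "hwe" in config.stages:
            settings = ChainSettings(
                config.hwe_dememorization, config.hwe_batches, config.hwe_iterations
            )
            results = hwe_test_dataset(ds, settings, seed=stage_seed["hwe"])
            testable = [r for r in results if r.testable]
            flags = sequential_bonferroni([r.p_value for r in testable], config.alpha)
            flag_map = {id(r): f for r, f in zip(testable, flags)}
            report.tables["hwe"] = pd.DataFrame(
                {
                    "locus": r.locus,
                    "scope": r.scope,
                    "n": r.n_individuals,
                    "p_value": r.p_value,
                    "mc_se": r.mc_se,
                    "testable": r.testable,
                    "deviates_raw": (r.p_value < config.alpha) if r.testable else False,
                    "deviates_holm": flag_map.get(id(r), False),
                    "note": r.note,
                }
                for r in results
            )
        if "fst" in config.stages:
            fst, fst_p = fst_matrix(
                ds, permutations=config.fst_permutations, seed=stage_seed["fst"]
            )
            report.tables["fst"] = _matrix_table(fst, fst_p)
        if "amova" in config.stages:
            amova = amova_three_level(
                ds, permutations=config.amova_permutations, seed=stage_seed["amova"]
            )
            report.tables["amova"] = amova.to_dataframe()
            report.summary["amova_indices"] = {
                "F_CT": amova.f_ct, "F_SC": amova.f_sc, "F_ST": amova.f_st,
                **{f"p_{k}": v for k, v in amova.p_values.items()},
            }
        if "ibd_euclidean" in config.stages or "ibd_landscape" in config.stages:
            if fst is None:
                fst, _ = fst_matrix(
                    ds, permutations=config.fst_permutations, seed=stage_seed["fst"]
                )
            sites = [ds.site(p) for p in ds.populations]
            weightm = pair_weight_matrix(
                ds, labels=ds.populations, rule=config.weight_rule
            )
        if "ibd_euclidean" in config.stages:
            eu = euclidean_matrix(sites).reorder(fst.labels)
            problem = MatrixRegressionProblem(fst, {"euclidean": eu}, weightm)
            res = model_average(
                problem, B=config.mrmpa_permutations, seed=stage_seed["ibd_euclidean"]
            )
            report.tables["ibd_euclidean_models"] = res.models
            report.tables["ibd_euclidean_predictors"] = res.predictors
            report.summary["ibd_euclidean"] = {
                "p": float(res.models.loc[res.models["model"] == "euclidean", "perm_p"].iloc[0]),
                "shapiro_w": res.shapiro_w, "shapiro_p": res.shapiro_p,
            }
        if "ibd_landscape" in config.stages:
            if config.raster is not None:
                raster = read_ascii_grid(config.raster)
            else:
                layers = read_feature_layers(config.features)
                xs = [s.easting for s in sites]
                ys = [s.northing for s in sites]
                pad = 2 * config.buffer_km * 1000.0
                raster = build_cost_raster(
                    HabitatRule(layers, config.buffer_km, config.outside_penalty),
                    (min(xs) - pad, min(ys) - pad, max(xs) + pad, max(ys) + pad),
                    config.resolution,
                )
            cwdd = least_cost_matrix(raster, sites).reorder(fst.labels)
            predictors: dict[str, PairwiseMatrix] = {"CWDD": cwdd}
            for var in config.climate_variables:
                predictors[var] = bray_curtis_matrix(sites, var).reorder(fst.labels)
            problem = MatrixRegressionProblem(fst, predictors, weightm)
            res = model_average(
                problem, B=config.mrmpa_permutations, seed=stage_seed["ibd_landscape"]
            )
            report.tables["ibd_landscape_models"] = res.models
            report.tables["ibd_landscape_predictors"] = res.predictors
            report.summary["ibd_landscape"] = {
                "best_model": list(res.best_model),
                "shapiro_w": res.shapiro_w, "shapiro_p": res.shapiro_p,
                "n_pairs": res.n_pairs, "n_dropped": res.n_dropped,
            }
        caught = [str(w.message) for w in wlog]

    report.summary["warnings"] = caught
    report.summary["row_counts"] = {k: len(v) for k, v in report.tables.items()}
    report.write(config.output_dir)
    return report


def _matrix_table(fst: PairwiseMatrix, pvals: PairwiseMatrix) -> pd.DataFrame:
    rows = []
    for a, b in fst.pairs():
        rows.append({"pop_a": a, "pop_b": b, "fst": fst[a, b], "p": pvals[a, b]})
    return pd.DataFrame(rows)


def compare_species(reports: Sequence[RunReport]) -> pd.DataFrame:
    """Side-by-side per-cohort diversity means ± SE and HWE-deviation counts."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    panels = [set(r.summary.get("loci", [])) for r in reports]
    shared = set.intersection(*panels) if all(panels) else set()
    if panels and any(p != panels[0] for p in panels):
        warnings.warn(
            f"cohorts were typed at different locus panels; {len(shared)} loci "
            "are shared — per-cohort means still cover each cohort's own panel"
        )
    rows = []
    for r in reports:
        cohort = r.config.get("cohort") or r.config.get("output_dir", "?")
        row: dict[str, Any] = {"cohort": cohort}
        div = r.tables.get("diversity")
        if div is not None:
            agg = div.iloc[-1]
            for col in ("A", "A_R", "H_O", "uH_E"):
                row[col] = agg[col]
                row[f"{col}_se"] = agg.get(f"{col}_se", math.nan)
            row["individuals"] = agg["individuals"]
        hwe = r.tables.get("hwe")
        if hwe is not None:
            row["hwe_deviations_raw"] = int(hwe["deviates_raw"].sum())
            row["hwe_deviations_holm"] = int(hwe["deviates_holm"].sum())
        rows.append(row)
    return pd.DataFrame(rows)
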
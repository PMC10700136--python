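"""Pipeline orchestration: enrich -> train -> predict -> gap -> ageotype ->
[fiba -> retrain] -> associate/survival, with a reproducibility manifest.

Every artifact is written deterministically (fixed float formatting,
seeded randomness), and the manifest records the SHA-256 of each output,
the configuration snapshot and the seed, so re-running an identical
configuration reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .agegap import GapConfig, compute_age_gaps, gaps_to_wide, zscore_gaps
from .ageotypes import AgeotypeConfig, cluster_ageotypes, flag_extreme_agers
from .clocks import ClockConfig, CohortData, predict_age, train_bagged_clock
from .enrichment import (
    DEFAULT_ORGAN_MAP,
    DEFAULT_ORGANS,
    ExpressionMatrix,
    build_protein_sets,
    call_enriched_genes,
    collapse_to_organs,
    normalize_expression,
    qc_filter_panel,
)
from .fiba import FibaConfig, compute_fiba, select_fiba_plus, train_cognition_model
from .simulate import SimulationConfig, simulate_inputs
from .stats import adjust_family, cox_ph_association, linear_association

logger = logging.getLogger(__name__)

TOOL_VERSION = "0.1.0"

ALL_STAGES = (
    "simulate", "enrich", "train", "predict", "gap", "ageotype",
    "fiba", "associate", "survival",
)


@dataclass
class EnrichmentConfig:
    fold_threshold: float = 4.0
    min_expression: float = 1.0
    max_cv: float = 0.15
    min_cross_version_r: float = 0.5
    normalize: bool = True
    tissue_summary: str = "median"
    organs_in_scope: tuple[str, ...] = DEFAULT_ORGANS


@dataclass
class PipelineConfig:
    outdir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "enrich", "train", "predict", "gap")
    # input paths (unused when the simulate stage is enabled)
    expression_path: str | None = None
    tissue_map_path: str | None = None
    panel_path: str | None = None
    proteins_path: str | None = None
    meta_path: str | None = None
    #: models to train; None = every catalog set (organs + organismal + conventional)
    models: tuple[str, ...] | None = None
    traits: tuple[str, ...] = ()
    survival_endpoints: tuple[tuple[str, str], ...] = ()  # (time_col, event_col)
    fiba_model: str = "brain"
    fiba_trait: str = "cdr"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    clock: ClockConfig = field(default_factory=ClockConfig)
    gap: GapConfig = field(default_factory=GapConfig)
    ageotype: AgeotypeConfig = field(default_factory=AgeotypeConfig)
    fiba: FibaConfig = field(default_factory=FibaConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        deps = {
            "train": "enrich", "predict": "train", "gap": "predict",
            "ageotype": "gap", "fiba": "gap", "associate": "gap", "survival": "gap",
        }
        for stage in self.stages:
            dep = deps.get(stage)
            if dep and dep not in self.stages:
                raise ValueError(f"stage {stage!r} requires {dep!r}")
        if "simulate" not in self.stages and "enrich" in self.stages:
            for attr in ("expression_path", "tissue_map_path", "panel_path",
                         "proteins_path", "meta_path"):
                if getattr(self, attr) is None:
                    raise ValueError(f"{attr} required when simulate stage is disabled")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        from .simulate import SurvivalSpec, TraitSpec

        if "simulation" in d and isinstance(d["simulation"], dict):
            sim = dict(d["simulation"])
            if "traits" in sim:
                sim["traits"] = tuple(TraitSpec(**t) for t in sim["traits"])
            if isinstance(sim.get("survival"), dict):
                sim["survival"] = SurvivalSpec(**sim["survival"])
            d["simulation"] = SimulationConfig(**sim)
        for key, klass in (
            ("enrichment", EnrichmentConfig), ("clock", ClockConfig),
            ("gap", GapConfig), ("ageotype", AgeotypeConfig), ("fiba", FibaConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        for key in ("stages", "models", "traits"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "survival_endpoints" in d:
            d["survival_endpoints"] = tuple(tuple(x) for x in d["survival_endpoints"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": TOOL_VERSION,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "status": "running",
    }
    artifacts: dict[str, Path] = {}

    def emit(stage: str, name: str, path: Path) -> None:
        manifest["stages"].setdefault(stage, {})[name] = _sha256(path)
        artifacts[name] = path

    expr = panel = cohort = catalog = None
    models: dict[str, object] = {}
    predictions: dict[str, object] = {}
    gaps_long: pd.DataFrame | None = None

    try:
        if "simulate" in config.stages:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            expr, panel, cohort, truth = simulate_inputs(sim)
            oio.write_gct(expr.values, outdir / "expression.gct")
            oio.write_tissue_map(expr.sample_to_tissue, outdir / "tissue_map.tsv")
            panel.to_csv(outdir / "panel.csv", index=False, float_format=oio.FLOAT_FORMAT)
            oio.write_proteins_raw(cohort.proteins, outdir / "proteins.csv")
            cohort.meta.to_csv(outdir / "meta.csv", float_format=oio.FLOAT_FORMAT)
            truth_small = {
                "gene_organ": truth.gene_organ,
                "trait_drivers": truth.trait_drivers,
                "theta": truth.theta,
                "seed": truth.seed,
            }
            (outdir / "truth.json").write_text(json.dumps(truth_small, indent=1, sort_keys=True))
            truth.offsets.to_csv(outdir / "offsets.tsv", sep="\t", float_format=oio.FLOAT_FORMAT)
            for name in ("expression.gct", "tissue_map.tsv", "panel.csv",
                         "proteins.csv", "meta.csv", "truth.json", "offsets.tsv"):
                emit("simulate", name, outdir / name)
        else:
            expr = oio.read_expression(config.expression_path, config.tissue_map_path)
            panel = pd.read_csv(config.panel_path)
            cohort = oio.read_cohort(config.proteins_path, config.meta_path)

        if "enrich" in config.stages:
            ec = config.enrichment
            e = normalize_expression(expr) if ec.normalize else expr
            organ_map = {o: DEFAULT_ORGAN_MAP[o] for o in ec.organs_in_scope}
            organ_expr = collapse_to_organs(e, organ_map, ec.tissue_summary)
            enr = call_enriched_genes(organ_expr, ec.fold_threshold, ec.min_expression)
            qc_panel = qc_filter_panel(panel, ec.max_cv, ec.min_cross_version_r)
            catalog = build_protein_sets(enr, qc_panel, ec.organs_in_scope, ec.fold_threshold)
            enr_out = enr.reset_index(names="gene")
            oio.write_table(enr_out, outdir / "enrichment.tsv")
            oio.write_catalog(catalog, outdir / "catalog.json")
            emit("enrich", "enrichment.tsv", outdir / "enrichment.tsv")
            emit("enrich", "catalog.json", outdir / "catalog.json")

        if "train" in config.stages:
            names = config.models if config.models is not None else catalog.model_names()
            healthy = (
                cohort.meta["healthy"].astype(bool)
                if "healthy" in cohort.meta.columns
                else pd.Series(True, index=cohort.meta.index)
            )
            train_cohort = cohort.subset(healthy)
            cc = dataclasses.replace(config.clock, seed=config.seed)
            for name in names:
                probes = catalog.probes_for(name)
                if not probes:
                    logger.warning("model %r skipped: empty probe set", name)
                    continue
                models[name] = train_bagged_clock(train_cohort, probes, cc, model_name=name)
                path = outdir / f"model_{name}.json"
                oio.write_model(models[name], path)
                emit("train", path.name, path)

        if "predict" in config.stages:
            frames = []
            for name, model in models.items():
                predictions[name] = predict_age(model, cohort)
                frames.append(predictions[name].to_frame().reset_index())
            pred_long = pd.concat(frames, ignore_index=True)
            oio.write_table(pred_long, outdir / "pred.tsv")
            emit("predict", "pred.tsv", outdir / "pred.tsv")

        if "gap" in config.stages:
            frames = []
            for name, pred in predictions.items():
                g = compute_age_gaps(
                    pred.mean_prediction,
                    cohort.age,
                    cohort.meta["cohort"].to_numpy(),
                    name,
                    config.gap,
                    subject_ids=cohort.subject_ids,
                )
                frames.append(zscore_gaps(g, config.gap))
            gaps_long = pd.concat(frames, ignore_index=True)
            oio.write_table(gaps_long, outdir / "gaps.tsv")
            emit("gap", "gaps.tsv", outdir / "gaps.tsv")

        if "ageotype" in config.stages:
            wide = gaps_to_wide(gaps_long)
            ac = dataclasses.replace(config.ageotype, seed=config.seed)
            flags = flag_extreme_agers(wide, ac)
            assign = cluster_ageotypes(wide, flags, ac)
            out = assign.reset_index(names="subject")
            oio.write_table(out, outdir / "ageotypes.tsv")
            emit("ageotype", "ageotypes.tsv", outdir / "ageotypes.tsv")

        if "fiba" in config.stages:
            fc = dataclasses.replace(config.fiba, seed=config.seed)
            model = models[config.fiba_model]
            result = compute_fiba(model, cohort, config.fiba_trait, fc)
            oio.write_table(result.table, outdir / f"fiba_{config.fiba_model}.tsv")
            emit("fiba", f"fiba_{config.fiba_model}.tsv", outdir / f"fiba_{config.fiba_model}.tsv")
            plus = select_fiba_plus(result, fc)
            if plus:
                healthy = (
                    cohort.meta["healthy"].astype(bool)
                    if "healthy" in cohort.meta.columns
                    else pd.Series(True, index=cohort.meta.index)
                )
                cc = dataclasses.replace(config.clock, seed=config.seed)
                cog = train_cognition_model(cohort.subset(healthy), plus, cc, config.fiba_model)
                path = outdir / f"model_{cog.model_name}.json"
                oio.write_model(cog, path)
                emit("fiba", path.name, path)
            else:
                logger.warning("empty FIBA+ set; no second-generation model trained")

        if "associate" in config.stages:
            rows = []
            for trait in config.traits:
                fam = []
                for name in models:
                    sub = gaps_long[gaps_long["model"] == name]
                    aligned = cohort.meta.loc[sub["subject"]]
                    fam.append(
                        linear_association(
                            sub["z_gap"].to_numpy(),
                            aligned[trait].to_numpy(dtype=float),
                            aligned["age"].to_numpy(dtype=float),
                            aligned["sex"].to_numpy(dtype=float),
                            model_name=name,
                            trait_name=trait,
                        )
                    )
                adjust_family(fam)
                rows.extend(fam)
            assoc = pd.DataFrame(
                [
                    {
                        "model": r.model_name, "trait": r.trait, "effect": r.effect,
                        "se": r.se, "ci_low": r.ci95[0], "ci_high": r.ci95[1],
                        "p": r.p, "q": r.q, "n": r.n,
                    }
                    for r in rows
                ]
            )
            oio.write_table(assoc, outdir / "associations.tsv")
            emit("associate", "associations.tsv", outdir / "associations.tsv")

        if "survival" in config.stages:
            rows = []
            for time_col, event_col in config.survival_endpoints:
                for name in models:
                    sub = gaps_long[gaps_long["model"] == name]
                    aligned = cohort.meta.loc[sub["subject"]]
                    res = cox_ph_association(
                        sub["z_gap"].to_numpy(),
                        aligned[time_col].to_numpy(dtype=float),
                        aligned[event_col].to_numpy(dtype=float),
                        aligned["age"].to_numpy(dtype=float),
                        aligned["sex"].to_numpy(dtype=float),
                        model_name=name,
                    )
                    rows.append(
                        {
                            "model": name, "endpoint": event_col,
                            "hazard_ratio": res.hazard_ratio,
                            "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                            "p": res.p, "n_events": res.n_events,
                            "n_subjects": res.n_subjects,
                        }
                    )
            surv = pd.DataFrame(rows)
            oio.write_table(surv, outdir / "survival.tsv")
            emit("survival", "survival.tsv", outdir / "survival.tsv")

        manifest["status"] = "complete"
    except Exception:
        manifest["status"] = "failed"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
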
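"""End-to-end orchestration: (load | simulate) -> preprocess -> normalize
-> fit -> count -> enrich, with a machine-readable run report.

The pipeline is a pure function of (inputs, config, seed): identical
configurations produce byte-identical reports.  Intermediates are
written as TSV next to the JSON report when an output directory is
given.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import enrichment_frame, fisher_enrichment
from .io import (
    AnnotationTable,
    DesignTable,
    SpotMatrix,
    ValidationError,
    read_annotation,
    read_design,
    read_directions,
    read_gmt,
    read_spot_table,
    write_annotation,
    write_design,
    write_spot_table,
)
from .models import (
    COEFFICIENTS,
    count_significant,
    fit_spot_models,
    significant_molecules,
    standard_workflow,
)
from .preprocess import ZeroPolicy, compute_class_proportions, replace_zeros
from .simulate import SimulationConfig, config_from_dict, simulate_experiment, truth_effect_table
from .tmm import normalize

log = logging.getLogger("dige_mm")


@dataclass
class PipelineConfig:
    """Everything one run needs; either file inputs or a simulation block."""

    matrix_path: Optional[str] = None
    design_path: Optional[str] = None
    annotation_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    genesets_path: Optional[str] = None
    directions_path: Optional[str] = None
    workflow: str = "tmm"
    tests: str = "wald"
    trim_m: float = 0.30
    trim_a: float = 0.05
    min_kept: int = 10
    prior: float = 0.5
    alpha: float = 0.05
    alpha_strict: float = 0.01
    out_dir: Optional[str] = None
    seed: Optional[int] = None  # overrides simulation.seed when set

    def validate(self) -> None:
        has_files = any([self.matrix_path, self.design_path, self.annotation_path])
        if has_files and self.simulation is not None:
            raise ValidationError(
                "config provides both input files and a simulation block; choose one"
            )
        if not has_files and self.simulation is None:
            raise ValidationError("config needs input files or a simulation block")
        if has_files and not all(
            [self.matrix_path, self.design_path, self.annotation_path]
        ):
            raise ValidationError("file input requires matrix, design and annotation paths")
        if self.workflow not in ("tmm", "standard"):
            raise ValidationError(f"workflow must be 'tmm' or 'standard', got {self.workflow!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if isinstance(raw.get("simulation"), dict):
            raw["simulation"] = config_from_dict(raw["simulation"])
        return cls(**raw)

    def to_dict(self) -> dict:
        def plain(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {f.name: plain(getattr(v, f.name)) for f in dataclasses.fields(v)}
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if isinstance(v, tuple):
                return [plain(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return plain(self)


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation)
        if config.seed is not None:
            sim.seed = config.seed
        matrix, design, annotation, truth = simulate_experiment(sim)
        return matrix, design, annotation, truth
    matrix = read_spot_table(config.matrix_path)
    design = read_design(config.design_path)
    annotation = read_annotation(config.annotation_path)
    return matrix, design, annotation, None


def _count_tables(results, annotation, alpha, alpha_strict) -> dict:
    """Per-coefficient counts at p<alpha, p<alpha_strict and q<alpha."""
    thresholds = {
        f"p<{alpha:g}": ("p", alpha),
        f"p<{alpha_strict:g}": ("p", alpha_strict),
        f"q<{alpha:g}": ("q", alpha),
    }
    out: dict = {coef: {} for coef in COEFFICIENTS}
    unique: dict = {coef: {} for coef in COEFFICIENTS}
    for label, (measure, a) in thresholds.items():
        counts = count_significant(results, annotation, alpha=a, measure=measure)
        for coef in COEFFICIENTS:
            out[coef][label] = counts["per_coefficient"][coef]["n_spots"]
            unique[coef][label] = counts["per_coefficient"][coef]["n_unique_ids"]
    return {"spots": out, "unique_ids": unique}


def _percent_reduction(spot_counts: dict, alpha: float, alpha_strict: float) -> dict:
    """100 * (1 - n_strict / n_loose) per coefficient, 1 decimal."""
    out = {}
    loose, strict = f"p<{alpha:g}", f"p<{alpha_strict:g}"
    for coef, counts in spot_counts.items():
        n_loose = counts[loose]
        out[coef] = (
            round(100.0 * (1.0 - counts[strict] / n_loose), 1) if n_loose else None
        )
    return out


def _fit(config: PipelineConfig, matrix, design, annotation):
    positive = replace_zeros(matrix, ZeroPolicy())
    if config.workflow == "standard":
        norm = None
        results = standard_workflow(matrix, design, prior=config.prior)
    else:
        norm = normalize(
            positive,
            annotation,
            trim_m=config.trim_m,
            trim_a=config.trim_a,
            min_kept=config.min_kept,
            prior=config.prior,
        )
        results = fit_spot_models(norm, design, tests=config.tests)
    return positive, norm, results


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (JSON-serializable)."""
    config.validate()
    matrix, design, annotation, truth = _load_inputs(config)
    design.validate_against(matrix)
    annotation.validate_against(matrix)
    log.info("loaded matrix: %d spots x %d gels", matrix.n_spots, matrix.n_gels)

    proportions = compute_class_proportions(matrix, annotation)
    positive, norm, results = _fit(config, matrix, design, annotation)
    counts = _count_tables(results, annotation, config.alpha, config.alpha_strict)
    n_failed = int((~results.variance_components["converged"]).sum())

    report: dict = {
        "software": {"name": "dige-mm", "version": __version__},
        "seed": config.seed if config.seed is not None else (
            config.simulation.seed if config.simulation else None
        ),
        "config": config.to_dict(),
        "stages": {
            "input": {"n_spots": matrix.n_spots, "n_gels": matrix.n_gels},
            "zeros_replaced": {
                "sample": int((matrix.sample == 0).sum()),
                "ips": int((matrix.ips == 0).sum()),
            },
            "class_proportions": json.loads(proportions.to_json(orient="index")),
            "model": {"method": results.method, "n_not_converged": n_failed},
        },
        "counts": counts,
        "percent_reduction_p05_to_p01": _percent_reduction(
            counts["spots"], config.alpha, config.alpha_strict
        ),
    }

    genesets = None
    if config.genesets_path:
        genesets = read_gmt(config.genesets_path)
        if config.directions_path:
            read_directions(config.directions_path, genesets)
        background = {
            g
            for s in matrix.spot_ids
            if (g := annotation.gene_of(s)) is not None
        }
        enrich_report = {}
        for coef in COEFFICIENTS:
            molecules = significant_molecules(
                results, annotation, coef, alpha=config.alpha, measure="p"
            )
            enr = fisher_enrichment(molecules, background, genesets)
            enrich_report[coef] = {
                r.set_id: {
                    "p_bh": r.p_bh,
                    "ratio": round(r.ratio, 3),
                    "z": None if r.z is None else round(r.z, 2),
                    "n_overlap": r.n_overlap,
                }
                for r in enr
            }
        report["enrichment"] = enrich_report

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_spot_table(matrix, out / "matrix.tsv")
        write_design(design, out / "design.tsv")
        write_annotation(annotation, out / "annotation.tsv")
        results.table.to_csv(out / "results.tsv", sep="\t", index=False)
        results.variance_components.to_csv(
            out / "variance_components.tsv", sep="\t", index=False
        )
        proportions.to_csv(out / "class_proportions.tsv", sep="\t")
        if norm is not None:
            norm.factor_table().to_csv(out / "tmm_factors.tsv", sep="\t", index=False)
            norm.normalized_frame().to_csv(out / "normalized_log2.tsv", sep="\t", index=False)
        if truth is not None:
            truth_effect_table(truth).to_csv(out / "truth_effects.tsv", sep="\t", index=False)
        if genesets is not None:
            for coef in COEFFICIENTS:
                molecules = significant_molecules(
                    results, annotation, coef, alpha=config.alpha, measure="p"
                )
                background = {
                    g for s in matrix.spot_ids if (g := annotation.gene_of(s)) is not None
                }
                enrichment_frame(
                    fisher_enrichment(molecules, background, genesets)
                ).to_csv(out / f"enrichment_{coef}.tsv", sep="\t", index=False)
        (out / "report.json").write_text(report_json(report))
    return report


def compare_workflows(config: PipelineConfig) -> dict:
    """Run the TMM and the standard workflow on identical input."""
    config.validate()
    reports = {}
    for workflow in ("tmm", "standard"):
        sub = dataclasses.replace(config, workflow=workflow, out_dir=None)
        reports[workflow] = run_pipeline(sub)
    comparison = {
        coef: {
            wf: reports[wf]["counts"]["spots"][coef] for wf in ("tmm", "standard")
        }
        for coef in COEFFICIENTS
    }
    report = {
        "software": reports["tmm"]["software"],
        "seed": reports["tmm"]["seed"],
        "config": config.to_dict(),
        "comparison": comparison,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "comparison.json").write_text(report_json(report))
    return report


def report_json(report: dict) -> str:
    """Canonical (byte-reproducible) JSON encoding of a report."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"
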
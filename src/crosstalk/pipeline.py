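"""End-to-end orchestration of the bulk and single-cell branches.

A :class:`PipelineConfig` (YAML-loadable) names the inputs, thresholds and
seeds; :func:`run_pipeline` executes the configured stages —

bulk branch:   differential expression -> pair regulation scenarios ->
               per-condition pair correlations + random-pair null ->
               correlation-shift classification -> infiltration comparison
single-cell:   type profiles -> high-expression calls -> directed network
               -> edge counts -> exclusiveness-ranked top edges

— and writes TSV/JSON/GraphML outputs plus a machine-readable run manifest
(inputs, seeds, thresholds, package version, produced files).  Rerunning
with the same config and seeds reproduces identical primary outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .correlation import ks_compare, pair_correlations, random_null, summarize_distribution
from .diffexpr import classify_pairs, fit_linear_model, moderate, select_de
from .infiltration import ADMIXTURE_TYPES, compare_infiltration_groups, quantile_split
from .io import (
    read_annotations,
    read_conditions,
    read_expression_matrix,
    read_infiltration,
)
from .pairs import load_pairs
from .scnet import (
    build_network,
    call_high,
    edge_counts,
    export_graphml,
    filter_involving,
    rank_edges,
    type_profiles,
)
from .shift import ShiftThresholds, shift_table
from .simulate import BulkCohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name for context."""


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for a pipeline run."""

    pairs: str
    outdir: str
    # bulk branch inputs
    bulk_matrix: str | None = None
    conditions: str | None = None
    infiltration: str | None = None
    # single-cell branch inputs
    sc_matrix: str | None = None
    sc_annotations: str | None = None
    # thresholds
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    use_fdr: bool = False
    shift_thresholds: dict[str, float] = field(default_factory=dict)
    k: float = 3.0
    stat_scope: str = "rest"
    top_fraction: float = 0.02
    quantile_q: float = 0.25
    focal_type: str | None = None
    # stochastic stages
    n_random: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not (0 < self.quantile_q < 0.5):
            raise ValueError("quantile_q must be in (0, 0.5)")
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.bulk_matrix is not None and self.n_random > 0 and self.seed is None:
            raise ValueError(
                "a seed is required for the random-pair null "
                "(set n_random: 0 to disable the stage)"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    skipped: list[str] = []

    def emit(name: str) -> Path:
        outputs.append(name)
        return outdir / name

    db = _stage("load_pairs")(load_pairs)(config.pairs)

    thr = ShiftThresholds(**config.shift_thresholds)

    if config.bulk_matrix and config.conditions:
        _run_bulk(config, db, thr, emit)
    else:
        skipped.append("bulk")
    if config.sc_matrix and config.sc_annotations:
        _run_single_cell(config, db, emit)
    else:
        skipped.append("single_cell")

    manifest = {
        "package": "crosstalk",
        "version": __version__,
        "config": config.to_dict(),
        "pair_db": db.summary(),
        "outputs": outputs,
        "skipped": skipped,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


@_stage("bulk")
def _run_bulk(config: PipelineConfig, db, thr: ShiftThresholds, emit) -> None:
    expr = read_expression_matrix(config.bulk_matrix)
    cond = read_conditions(config.conditions).reindex(expr.columns)
    if cond.isna().any():
        raise ValueError("every sample needs a condition label")
    cohort = BulkCohort(expression=expr, condition=cond)

    fit = fit_linear_model(cohort)
    de = moderate(fit)
    up, down = select_de(de, config.fc_threshold, config.p_threshold, config.use_fdr)
    de["direction"] = [
        "up" if g in up else "down" if g in down else "unchanged" for g in de.index
    ]
    de.rename_axis("gene").to_csv(emit("de.tsv"), sep="\t")
    classify_pairs(up, down, db).to_csv(emit("pair_scenarios.tsv"), sep="\t", index=False)

    rec_n = pair_correlations(cohort, db, "normal")
    rec_c = pair_correlations(cohort, db, "cancer")
    corr = pd.concat([rec_n, rec_c])
    corr.to_csv(emit("correlations.tsv"), sep="\t", index=False)

    summary: dict[str, Any] = {
        "specific_normal": dataclasses.asdict(summarize_distribution(rec_n)),
        "specific_cancer": dataclasses.asdict(summarize_distribution(rec_c)),
        "ks_normal_vs_cancer": dataclasses.asdict(ks_compare(rec_n["rho"], rec_c["rho"])),
    }
    if config.n_random > 0:
        n_random = min(config.n_random, db.n_noninteracting())
        null_n = random_null(cohort, db, n_random, config.seed, "normal")
        null_c = random_null(cohort, db, n_random, config.seed, "cancer")
        pd.concat([null_n, null_c]).to_csv(
            emit("random_null.tsv"), sep="\t", index=False
        )
        summary["random_normal"] = dataclasses.asdict(summarize_distribution(null_n))
        summary["random_cancer"] = dataclasses.asdict(summarize_distribution(null_c))
        summary["ks_specific_vs_random_cancer"] = dataclasses.asdict(
            ks_compare(rec_c["rho"], null_c["rho"])
        )
    (emit("summary.json")).write_text(json.dumps(summary, indent=2, sort_keys=True))

    shifts = shift_table(rec_n, rec_c, thr)
    shifts.to_csv(emit("shift.tsv"), sep="\t", index=False)

    if config.infiltration:
        table = read_infiltration(config.infiltration)
        report: dict[str, Any] = {}
        for cell_type in ADMIXTURE_TYPES:
            if cell_type not in table.columns:
                continue
            split = quantile_split(table, cell_type, config.quantile_q)
            qq, ks = compare_infiltration_groups(cohort, db, split)
            qq.to_csv(emit(f"infiltration_{cell_type}_qq.tsv"), sep="\t", index=False)
            report[cell_type] = {
                "n_high": len(split[0]),
                "n_low": len(split[1]),
                **dataclasses.asdict(ks),
            }
        (emit("infiltration.json")).write_text(json.dumps(report, indent=2, sort_keys=True))


@_stage("single_cell")
def _run_single_cell(config: PipelineConfig, db, emit) -> None:
    matrix = read_expression_matrix(config.sc_matrix)
    ann = read_annotations(config.sc_annotations)
    profiles, _ = type_profiles(matrix, ann)
    calls = call_high(matrix, ann, k=config.k, stat_scope=config.stat_scope)
    edges = build_network(calls, db)
    edges.to_csv(emit("edges.tsv"), sep="\t", index=False)
    edge_counts(edges, types=list(profiles.columns)).rename_axis("sender").to_csv(
        emit("edge_counts.tsv"), sep="\t"
    )
    if len(edges):
        focal = edges if config.focal_type is None else filter_involving(edges, config.focal_type)
        if len(focal):
            ranked = rank_edges(focal, profiles, config.top_fraction)
            ranked.to_csv(emit("top_edges.tsv"), sep="\t", index=False)
        export_graphml(edges, emit("network.graphml"))
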
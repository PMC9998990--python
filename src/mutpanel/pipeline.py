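"""Orchestration of discovery and validation runs.

``run_discovery`` executes the full training-side chain — variant filtering,
binary matrix, gene-prevalence filter, outcome binarization, backward search,
panel choice, MT/WT evaluation — and writes every artifact plus a config
snapshot to the output directory.  ``run_validation`` applies a fixed panel
to an independent cohort with no refitting of any selection step.

All written artifacts are deterministic functions of (inputs, config, seed):
JSON is emitted with sorted keys and no timestamps, so identical runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .cohort_io import (
    Cohort,
    FilterConfig,
    FilterReport,
    TableDialect,
    assemble_cohort,
    read_clinical_table,
    read_mutation_table,
)
from .feature_selection import (
    RfConfig,
    SelectionTrace,
    StepSchedule,
    binarize_outcome,
    choose_best_subset,
    sbs_select,
)
from .mutation_features import build_binary_matrix, prevalence_filter
from .panel_classifier import GeneSetRule, PanelModel, classify_cohort, stratify_by_count
from .survival_eval import evaluate_mt_wt

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a discovery or validation run needs, in one place."""

    out_dir: str | Path = "run_out"
    mutations_path: str | Path | None = None
    clinical_path: str | Path | None = None
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    rf_cfg: RfConfig = field(default_factory=RfConfig)
    schedule: StepSchedule = field(default_factory=StepSchedule)
    min_prevalence_samples: int = 3
    binarization_scheme: str = "alive_at_horizon"
    horizon_months: float = 12.0
    threshold_k: int = 2
    tie_tolerance: float = 0.0
    rules: list[GeneSetRule] = field(default_factory=list)
    seed: int = 0

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["mutations_path"] = str(self.mutations_path) if self.mutations_path else None
        d["clinical_path"] = str(self.clinical_path) if self.clinical_path else None
        d["rules"] = [
            {
                "name": r.name,
                "genes": sorted(r.genes),
                "min_mutated": r.min_mutated,
                "positive_label": r.positive_label,
                "negative_label": r.negative_label,
            }
            for r in self.rules
        ]
        return d


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_cohort(cfg: RunConfig, dialect: TableDialect | None = None) -> tuple[Cohort, FilterReport]:
    """Read the configured mutation + clinical tables into a filtered Cohort."""
    if cfg.mutations_path is None or cfg.clinical_path is None:
        raise ValueError("RunConfig needs mutations_path and clinical_path to load a cohort")
    mutations = read_mutation_table(cfg.mutations_path, dialect)
    clinical = read_clinical_table(cfg.clinical_path)
    return assemble_cohort(mutations, clinical, cfg.filter_cfg)


def run_discovery(
    cfg: RunConfig, cohort: Cohort | None = None
) -> tuple[PanelModel, SelectionTrace, dict]:
    """Discover a gene panel on a training cohort and evaluate it in place.

    Stages (any failure aborts naming the stage; artifacts written so far are
    left in the output directory): filter -> matrix -> prevalence filter ->
    binarize -> backward search -> panel choice -> MT/WT evaluation.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rf_cfg = dataclasses.replace(cfg.rf_cfg, seed=cfg.seed)
    stage = "load"
    try:
        if cohort is None:
            cohort, filter_report = load_cohort(cfg)
            _write_json(out / "filter_report.json", json.loads(filter_report.to_json()))
        stage = "matrix"
        matrix = build_binary_matrix(cohort)
        stage = "prevalence_filter"
        matrix = prevalence_filter(matrix, cfg.min_prevalence_samples)
        matrix.to_tsv(out / "matrix.tsv")
        stage = "binarize_outcome"
        labels = binarize_outcome(
            cohort.clinical, cfg.binarization_scheme, cfg.horizon_months
        )
        stage = "backward_search"
        trace = sbs_select(matrix, labels, rf_cfg, cfg.schedule)
        (out / "trace.json").write_text(trace.to_json() + "\n")
        stage = "choose_panel"
        genes = choose_best_subset(trace, cfg.tie_tolerance)
        panel = PanelModel(genes=tuple(genes), threshold_k=cfg.threshold_k, name="discovered")
        (out / "panel.json").write_text(panel.to_json() + "\n")
        (out / "panel_genes.txt").write_text("\n".join(panel.genes) + "\n")
        stage = "evaluate"
        calls = classify_cohort(matrix, panel, cfg.rules)
        calls.to_csv(out / "calls.tsv", sep="\t")
        report = evaluate_mt_wt(
            cohort.clinical_frame()[["time_months", "event"]],
            calls,
            auc_scheme=labels.scheme,
            auc_outcome=labels.labels,
            auc_sample_ids=labels.sample_ids,
        )
        report["panel"] = {"genes": list(panel.genes), "threshold_k": panel.threshold_k}
        report["best_cv_accuracy"] = max(trace.accuracies())
        report["outcome_scheme"] = labels.scheme
        report["seed"] = cfg.seed
        # audit trail: discovery touches only the training inputs
        report["inputs_read"] = (
            [str(cfg.mutations_path), str(cfg.clinical_path)]
            if cfg.mutations_path
            else ["<in-memory cohort>"]
        )
        report["count_strata_sizes"] = {
            str(k): len(v) for k, v in stratify_by_count(matrix, panel).items()
        }
        _write_json(out / "report.json", report)
        _write_json(out / "config_snapshot.json", cfg.snapshot())
    except Exception as err:
        raise RuntimeError(f"discovery failed at stage {stage!r}: {err}") from err
    return panel, trace, report


def run_validation(cfg: RunConfig, panel: PanelModel, cohort: Cohort | None = None) -> dict:
    """Apply a fixed panel to a validation cohort: classify, stratify and run
    the survival evaluation.  No selection step is refit."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if cohort is None:
            cohort, filter_report = load_cohort(cfg)
            _write_json(out / "filter_report.json", json.loads(filter_report.to_json()))
        stage = "matrix"
        matrix = build_binary_matrix(cohort)
        stage = "classify"
        calls = classify_cohort(matrix, panel, cfg.rules)
        calls.to_csv(out / "calls.tsv", sep="\t")
        stage = "evaluate"
        labels = binarize_outcome(
            cohort.clinical, cfg.binarization_scheme, cfg.horizon_months
        )
        report = evaluate_mt_wt(
            cohort.clinical_frame()[["time_months", "event"]],
            calls,
            auc_scheme=labels.scheme,
            auc_outcome=labels.labels,
            auc_sample_ids=labels.sample_ids,
        )
        report["panel"] = {"genes": list(panel.genes), "threshold_k": panel.threshold_k}
        report["outcome_scheme"] = labels.scheme
        report["seed"] = cfg.seed
        report["inputs_read"] = (
            [str(cfg.mutations_path), str(cfg.clinical_path)]
            if cfg.mutations_path
            else ["<in-memory cohort>"]
        )
        report["count_strata_sizes"] = {
            str(k): len(v) for k, v in stratify_by_count(matrix, panel).items()
        }
        _write_json(out / "report.json", report)
        _write_json(out / "config_snapshot.json", cfg.snapshot())
    except Exception as err:
        raise RuntimeError(f"validation failed at stage {stage!r}: {err}") from err
    return report
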
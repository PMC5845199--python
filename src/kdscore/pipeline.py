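"""End-to-end orchestration: cohort → scores → stratification → reports.

`evaluate_models_on_cohort` scores every selected model on every
patient, builds per-model confusion matrices (excluding, per model,
patients whose risk class is indeterminate or whose response label is
unknown), and computes diagnostic metrics with confidence intervals.
ROC AUC is computed on the ordinal score (total points; the number of
satisfied criteria for the combination rule) over patients with no
missing score inputs, since only for them is the total exact.

Exclusion is per model, never listwise: a patient missing only a
lymphocyte count still counts for every score that does not need it.

`run_pipeline` wraps this in a reproducible artifact bundle (cohort
echo, comparison table, accuracy table, JSON report, run log), written
atomically (write-then-rename) so a failed run leaves no truncated
files.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import __version__
from .cohort import Cohort, CohortSchema, read_cohort, write_cohort
from .compare import ComparisonTable, build_table2, write_comparison_csv
from .diagnostics import (ConfusionMatrix, DiagnosticReport, build_report,
                          confusion_from_predictions, round_report)
from .errors import PipelineError
from .scoring import (AnyModel, INDETERMINATE, MODEL_ORDER, ScoreResult,
                      builtin_models, score_patient)
from .simulate import SyntheticCohortConfig, generate_cohort


@dataclass
class ModelEvaluation:
    """Everything one model produced on one cohort."""

    model: str
    results: list[ScoreResult]
    confusion: ConfusionMatrix
    report: DiagnosticReport
    n_unlabeled: int
    excluded_ids: list[str] = field(default_factory=list)


def evaluate_models_on_cohort(cohort: Cohort,
                              models: Optional[dict[str, AnyModel]] = None,
                              ) -> dict[str, ModelEvaluation]:
    """Score, stratify and evaluate every model on a labeled cohort.

    Patients without a response label are excluded (counted per model
    as ``n_unlabeled``); patients a model cannot classify are excluded
    from that model's 2×2 table only.  Raises
    :class:`~kdscore.errors.PipelineError` if no patient is labeled.
    """
    models = models if models is not None else builtin_models()
    if not any(p.ivig_resistant is not None for p in cohort):
        raise PipelineError("no labeled patients in cohort")

    out: dict[str, ModelEvaluation] = {}
    for name, model in models.items():
        results = [score_patient(model, p) for p in cohort]
        labels = [p.ivig_resistant for p in cohort]
        classes = [r.risk_class for r in results]
        n_unlabeled = sum(1 for lab in labels if lab is None)

        # 2x2 over labeled, determinate patients
        cm = confusion_from_predictions(
            [lab for lab in labels if lab is not None],
            [c for lab, c in zip(labels, classes) if lab is not None])
        excluded_ids = [p.id for p, r in zip(cohort, results)
                        if p.ivig_resistant is not None and r.risk_class == INDETERMINATE]

        # AUC over labeled patients whose score inputs are complete
        scores, score_labels = [], []
        for p, r in zip(cohort, results):
            if p.ivig_resistant is not None and not r.missing_variables:
                scores.append(r.ordinal_score)
                score_labels.append(bool(p.ivig_resistant))
        rep = build_report(name, cm,
                           scores=scores if scores else None,
                           labels=score_labels if score_labels else None)
        out[name] = ModelEvaluation(model=name, results=results, confusion=cm,
                                    report=rep, n_unlabeled=n_unlabeled,
                                    excluded_ids=excluded_ids)
    return out


def conservation_holds(cohort_size: int, ev: ModelEvaluation) -> bool:
    """tp+fp+fn+tn + excluded + unlabeled must equal the cohort size."""
    cm = ev.confusion
    return cm.total + cm.n_excluded + ev.n_unlabeled == cohort_size


# ---------------------------------------------------------------------------
# run configuration and artifact bundle


@dataclass
class RunConfig:
    """One pipeline run: input, model options, output directory."""

    input_path: Optional[str] = None
    schema_path: Optional[str] = None
    synthetic: Optional[SyntheticCohortConfig] = None
    models: Sequence[str] = MODEL_ORDER
    missing_policy: str = INDETERMINATE
    kobayashi_cutoff: int = 3
    kawamura_combination: str = "both_required"
    denominator_mode: str = "within_group"
    output_dir: str = "kdscore_run"
    dp: int = 2

    def selected_models(self) -> dict[str, AnyModel]:
        registry = builtin_models(kobayashi_cutoff=self.kobayashi_cutoff,
                                  kawamura_combination=self.kawamura_combination,
                                  missing_policy=self.missing_policy)
        unknown = set(self.models) - set(registry)
        if unknown:
            raise PipelineError(f"unknown model(s): {sorted(unknown)}")
        return {name: registry[name] for name in self.models}


def load_run_cohort(config: RunConfig) -> Cohort:
    if (config.input_path is None) == (config.synthetic is None):
        raise PipelineError("exactly one of input_path and synthetic must be set")
    if config.input_path is not None:
        schema = CohortSchema.from_yaml(config.schema_path) if config.schema_path \
            else CohortSchema()
        return read_cohort(config.input_path, schema)
    return generate_cohort(config.synthetic)


def _atomic_write(path: str, writer) -> None:
    """Write via a temp file in the same directory, then rename."""
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".part")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def table3_rows(evaluations: dict[str, ModelEvaluation], dp: int = 2) -> list[dict[str, str]]:
    """Accuracy table rows (printed-style strings), in registry order."""
    return [round_report(ev.report, dp) for ev in evaluations.values()]


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute a full run and write the artifact bundle.

    Returns a mapping of artifact name to written path.  Outputs:
    ``cohort.csv`` (canonical-unit echo), ``table2.csv`` (group
    comparison, when both groups are present), ``table3.csv``
    (diagnostic accuracy), ``report.json`` (canonical machine output),
    ``run.log``.  Rerunning with the same config reproduces identical
    bytes.
    """
    cohort = load_run_cohort(config)
    models = config.selected_models()
    evaluations = evaluate_models_on_cohort(cohort, models)

    os.makedirs(config.output_dir, exist_ok=True)
    paths: dict[str, str] = {}
    log_lines = [f"kdscore {__version__}",
                 f"cohort: {cohort.provenance} (n={len(cohort)})",
                 f"models: {', '.join(models)}"]

    p = os.path.join(config.output_dir, "cohort.csv")
    _atomic_write(p, lambda fh: write_cohort(cohort, fh))
    paths["cohort"] = p

    table2: Optional[ComparisonTable] = None
    try:
        table2 = build_table2(cohort, denominator_mode=config.denominator_mode)
    except Exception as exc:  # single-group cohort: describe why, skip table
        log_lines.append(f"table2 skipped: {exc}")
    if table2 is not None:
        p = os.path.join(config.output_dir, "table2.csv")
        _atomic_write(p, lambda fh: write_comparison_csv(table2, fh))
        paths["table2"] = p

    rows = table3_rows(evaluations, config.dp)
    cols = ["model", "tp", "fp", "fn", "tn", "n_excluded",
            "sensitivity", "specificity", "ppv", "npv", "auc", "auc_95ci"]
    p = os.path.join(config.output_dir, "table3.csv")
    _atomic_write(p, lambda fh: fh.write(
        ",".join(cols) + "\n" +
        "".join(",".join(r[c] for c in cols) + "\n" for r in rows)))
    paths["table3"] = p

    report = {
        "kdscore_version": __version__,
        "config": {
            "input_path": config.input_path,
            "synthetic": None if config.synthetic is None else {
                "n": config.synthetic.n, "seed": config.synthetic.seed,
                "missingness": config.synthetic.missingness},
            "models": list(config.models),
            "missing_policy": config.missing_policy,
            "kobayashi_cutoff": config.kobayashi_cutoff,
            "kawamura_combination": config.kawamura_combination,
            "denominator_mode": config.denominator_mode,
            "dp": config.dp,
        },
        "cohort": {"n": len(cohort), "provenance": cohort.provenance},
        "models": {},
    }
    for name, ev in evaluations.items():
        cm = ev.confusion
        rep = ev.report
        report["models"][name] = {
            "counts": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                       "n_excluded": cm.n_excluded, "n_unlabeled": ev.n_unlabeled},
            "sensitivity": rep.sensitivity, "sensitivity_ci": rep.sensitivity_ci,
            "specificity": rep.specificity, "specificity_ci": rep.specificity_ci,
            "ppv": rep.ppv, "ppv_ci": rep.ppv_ci,
            "npv": rep.npv, "npv_ci": rep.npv_ci,
            "auc": rep.auc, "auc_ci": rep.auc_ci,
            "excluded_ids": ev.excluded_ids,
        }
        log_lines.append(
            f"{name}: tp={cm.tp} fp={cm.fp} fn={cm.fn} tn={cm.tn} "
            f"excluded={cm.n_excluded} unlabeled={ev.n_unlabeled}")
        for rid in ev.excluded_ids:
            missing = next(r.missing_variables for p_, r in zip(cohort, ev.results)
                           if p_.id == rid)
            log_lines.append(f"{name}: excluded {rid} (missing: {', '.join(missing)})")

    p = os.path.join(config.output_dir, "report.json")
    _atomic_write(p, lambda fh: fh.write(json.dumps(report, indent=2, sort_keys=True) + "\n"))
    paths["report"] = p

    p = os.path.join(config.output_dir, "run.log")
    _atomic_write(p, lambda fh: fh.write("\n".join(log_lines) + "\n"))
    paths["log"] = p
    return paths
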
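"""Diagnostic-accuracy statistics for risk stratification.

Builds 2×2 confusion matrices of high/low-risk classification against
the observed IVIG response, computes sensitivity, specificity, PPV and
NPV with Wilson score confidence intervals, and rank-based ROC AUC
with a DeLong asymptotic confidence interval.

Conventions
-----------
* tp = resistant & high risk, fp = responsive & high risk,
  fn = resistant & low risk, tn = responsive & low risk.
* A ratio with zero denominator is *undefined* and returned as
  ``None`` — never 0 and never an exception — so degenerate strata can
  still be reported.
* AUC is the tie-corrected rank statistic
  ``[#(pos > neg) + 0.5·#(pos = neg)] / (n_pos · n_neg)``, identical
  to the trapezoidal area under the empirical ROC curve through all
  score thresholds.
* Printed-style rounding operates on exact integer ratios with
  half-away-from-zero tie-breaking, so e.g. 359/479 prints as 0.75
  regardless of binary floating-point representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint

from .errors import InputError, UndefinedAUCError

Number = Union[int, float, Fraction]


@dataclass
class ConfusionMatrix:
    """2×2 counts of predicted risk class vs observed IVIG response."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    n_excluded: int = 0

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn", "n_excluded"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_from_predictions(labels: Sequence[Optional[bool]],
                               classes: Sequence[str]) -> ConfusionMatrix:
    """Tally (resistant-label, risk-class) pairs into a confusion matrix.

    ``labels`` are per-patient resistance indicators (``None`` =
    unknown); ``classes`` are ``high``/``low``/``indeterminate``.
    Patients with an unknown label or an indeterminate class increment
    ``n_excluded`` only.
    """
    if len(labels) != len(classes):
        raise InputError(f"length mismatch: {len(labels)} labels vs {len(classes)} classes")
    cm = ConfusionMatrix()
    for lab, cls in zip(labels, classes):
        if lab is None or cls == "indeterminate":
            cm.n_excluded += 1
        elif lab and cls == "high":
            cm.tp += 1
        elif lab and cls == "low":
            cm.fn += 1
        elif not lab and cls == "high":
            cm.fp += 1
        elif not lab and cls == "low":
            cm.tn += 1
        else:
            raise InputError(f"unknown risk class {cls!r}")
    return cm


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity, PPV, NPV as exact fractions (None = undefined)."""

    sensitivity: Optional[Fraction]
    specificity: Optional[Fraction]
    ppv: Optional[Fraction]
    npv: Optional[Fraction]


def _ratio(num: int, den: int) -> Optional[Fraction]:
    return Fraction(num, den) if den > 0 else None


def diagnostic_metrics(cm: ConfusionMatrix) -> Metrics:
    """Sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV tp/(tp+fp),
    NPV tn/(tn+fn); each ``None`` when its denominator is zero."""
    return Metrics(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
    )


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion k/n."""
    if n < 1 or not 0 <= k <= n:
        raise InputError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0 < level < 1:
        raise InputError(f"level must be in (0,1), got {level}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Tie-corrected rank AUC of an ordinal score for a binary label.

    Computed from midranks: with R the rank sum of the positives,
    ``AUC = (R - n_pos(n_pos+1)/2) / (n_pos * n_neg)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise InputError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined: need at least one positive and one negative")
    ranks = rankdata(scores)
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _midrank_placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components (placement values) per class."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    # V10_i = P(score_neg < pos_i) + 0.5 P(= pos_i); V01_j analogous
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def auc_ci_delong(scores: Sequence[float], labels: Sequence[bool],
                  level: float = 0.95) -> tuple[float, float]:
    """DeLong asymptotic confidence interval for the rank AUC.

    The variance is estimated from the empirical placement values of
    the two classes; the normal-theory interval is truncated to [0,1].
    With perfectly separated classes the empirical variance is zero and
    the interval collapses onto the point estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    auc = roc_auc(scores, labels)
    v10, v01 = _midrank_placements(scores, labels)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


# ---------------------------------------------------------------------------
# printed-style rounding


def round_half_away(x: Number, dp: int = 2) -> Decimal:
    """Round half away from zero on the exact rational value of ``x``.

    Accepts :class:`fractions.Fraction` (exact), ints, or floats (which
    are first re-read through their shortest decimal repr, so 0.75
    means the decimal 0.75 and not its binary neighbour).
    """
    if dp < 0:
        raise InputError("dp must be >= 0")
    if isinstance(x, (float, np.floating)):
        frac = Fraction(Decimal(repr(float(x))))
    else:
        frac = Fraction(x)
    scaled = frac * 10 ** dp
    q, r = divmod(abs(scaled.numerator), scaled.denominator)
    if 2 * r >= scaled.denominator:
        q += 1
    if scaled < 0:
        q = -q
    return Decimal(q).scaleb(-dp)


def format_proportion(x: Optional[Number], dp: int = 2) -> str:
    """Format a proportion for a printed report; undefined becomes '--'."""
    if x is None:
        return "--"
    return f"{round_half_away(x, dp):.{dp}f}"


@dataclass
class DiagnosticReport:
    """Per-model diagnostic accuracy in the shape of a published
    validation table: counts, the four proportions with Wilson CIs, and
    (when patient-level scores are available) the score AUC with its
    DeLong CI."""

    model: str
    counts: ConfusionMatrix
    sensitivity: Optional[float] = None
    sensitivity_ci: Optional[tuple[float, float]] = None
    specificity: Optional[float] = None
    specificity_ci: Optional[tuple[float, float]] = None
    ppv: Optional[float] = None
    ppv_ci: Optional[tuple[float, float]] = None
    npv: Optional[float] = None
    npv_ci: Optional[tuple[float, float]] = None
    auc: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None
    metrics_exact: Optional[Metrics] = field(default=None, repr=False)


def build_report(model: str, cm: ConfusionMatrix,
                 scores: Optional[Sequence[float]] = None,
                 labels: Optional[Sequence[bool]] = None,
                 level: float = 0.95) -> DiagnosticReport:
    """Assemble a :class:`DiagnosticReport` from counts (and optionally
    patient-level ordinal scores for the AUC)."""
    m = diagnostic_metrics(cm)
    rep = DiagnosticReport(model=model, counts=cm, metrics_exact=m)
    pairs = {
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
    }
    for name, (k, n) in pairs.items():
        val = getattr(m, name)
        if val is not None:
            setattr(rep, name, float(val))
            setattr(rep, name + "_ci", wilson_interval(k, n, level))
    if scores is not None and labels is not None:
        try:
            rep.auc = roc_auc(scores, labels)
            rep.auc_ci = auc_ci_delong(scores, labels, level)
        except UndefinedAUCError:
            pass
    return rep


def round_report(report: DiagnosticReport, dp: int = 2) -> dict[str, str]:
    """Printed-style view of a report: exact-rational rounding at ``dp``
    decimals, matching how validation tables are typeset."""
    m = report.metrics_exact or diagnostic_metrics(report.counts)
    out = {
        "model": report.model,
        "tp": str(report.counts.tp), "fp": str(report.counts.fp),
        "fn": str(report.counts.fn), "tn": str(report.counts.tn),
        "n_excluded": str(report.counts.n_excluded),
        "sensitivity": format_proportion(m.sensitivity, dp),
        "specificity": format_proportion(m.specificity, dp),
        "ppv": format_proportion(m.ppv, dp),
        "npv": format_proportion(m.npv, dp),
    }
    out["auc"] = format_proportion(report.auc, dp) if report.auc is not None else "--"
    if report.auc_ci is not None:
        lo, hi = report.auc_ci
        out["auc_95ci"] = f"{format_proportion(lo, dp)}-{format_proportion(hi, dp)}"
    else:
        out["auc_95ci"] = "--"
    return out
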
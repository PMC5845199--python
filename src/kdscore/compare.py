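"""Cohort description and resistant-vs-responsive group comparison.

Produces a per-variable summary table of the kind used to describe a
validation cohort: continuous variables as median (Q1, Q3) compared
with a two-sided Mann–Whitney U test; categorical variables as
n (%) compared with a chi-square test, switching to Fisher's exact
test when any expected cell count falls below a threshold (default 5).

Quantiles use linear interpolation between order statistics (the
default convention of the major statistical packages).  The
Mann–Whitney p-value uses scipy's implementation: exact for small
untied samples, otherwise a tie-corrected normal approximation.

Percentages can be computed ``within_group`` (each group's count over
its own size — the default) or over the ``total_cohort``, a layout
some published tables use where the two group percentages sum to the
overall prevalence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, TextIO, Union

import numpy as np
from scipy import stats

from .cohort import Cohort, PatientRecord, SIGN_FIELDS, derive_ratios
from .errors import InputError

RESISTANT, RESPONSIVE = "resistant", "responsive"


@dataclass
class GroupStats:
    """Per-group summary: continuous (median, q1, q3, n) or categorical (count, pct, n)."""

    n: int
    median: Optional[float] = None
    q1: Optional[float] = None
    q3: Optional[float] = None
    count: Optional[int] = None
    percent: Optional[float] = None


@dataclass
class VariableSummary:
    """One comparison-table row: per-group stats, p-value, test used."""

    variable: str
    kind: str  # "continuous" | "categorical"
    groups: dict[str, GroupStats] = field(default_factory=dict)
    p_value: Optional[float] = None
    test_used: Optional[str] = None  # mann_whitney | chi_square | fisher_exact


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return float(med), float(q1), float(q3)


def summarize_continuous(name: str,
                         values_by_group: dict[str, Sequence[float]]) -> VariableSummary:
    """Median (Q1, Q3) per group and a two-sided Mann–Whitney U p-value.

    Missing values (None/NaN) are excluded per group.  If a group has
    no non-missing values its stats and the p-value are absent.
    """
    if len(values_by_group) != 2:
        raise InputError("summarize_continuous expects exactly two groups")
    summary = VariableSummary(variable=name, kind="continuous")
    clean: dict[str, np.ndarray] = {}
    for g, vals in values_by_group.items():
        arr = np.asarray([v for v in vals if v is not None], dtype=float)
        arr = arr[~np.isnan(arr)]
        clean[g] = arr
        gs = GroupStats(n=len(arr))
        if len(arr):
            gs.median, gs.q1, gs.q3 = _quartiles(arr)
        summary.groups[g] = gs
    a, b = clean.values()
    if len(a) and len(b):
        combined = np.concatenate([a, b])
        if np.ptp(combined) == 0:
            # all values identical in both groups: no evidence of a shift
            summary.p_value = 1.0
        else:
            has_ties = len(np.unique(combined)) < len(combined)
            # exact null where feasible; tie-corrected normal approximation
            # (no continuity correction) otherwise
            method = "exact" if not has_ties and max(len(a), len(b)) <= 25 else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method=method, use_continuity=False)
            summary.p_value = float(res.pvalue)
        summary.test_used = "mann_whitney"
    return summary


def summarize_categorical(name: str,
                          present_by_group: dict[str, int],
                          sizes_by_group: dict[str, int],
                          denominator_mode: str = "within_group",
                          fisher_threshold: float = 5.0) -> VariableSummary:
    """Counts with percentages and a 2×2 chi-square / Fisher p-value.

    The chi-square statistic is computed without continuity correction;
    Fisher's exact test replaces it whenever any expected cell count is
    below ``fisher_threshold``.
    """
    if set(present_by_group) != set(sizes_by_group) or len(sizes_by_group) != 2:
        raise InputError("need matching group keys for counts and sizes (two groups)")
    if any(n <= 0 for n in sizes_by_group.values()):
        raise InputError("zero-size group")
    if denominator_mode not in ("within_group", "total_cohort"):
        raise InputError(f"unknown denominator_mode {denominator_mode!r}")
    total = sum(sizes_by_group.values())
    summary = VariableSummary(variable=name, kind="categorical")
    table = []
    for g in sizes_by_group:
        k, n = present_by_group[g], sizes_by_group[g]
        if not 0 <= k <= n:
            raise InputError(f"count {k} outside [0, {n}] for group {g!r}")
        denom = n if denominator_mode == "within_group" else total
        summary.groups[g] = GroupStats(n=n, count=k, percent=100.0 * k / denom)
        table.append([k, n - k])
    table = np.asarray(table)
    if table.sum() == 0:
        summary.p_value, summary.test_used = 1.0, "fisher_exact"
        return summary
    expected = stats.contingency.expected_freq(table)
    if (expected < fisher_threshold).any():
        summary.p_value = float(stats.fisher_exact(table)[1])
        summary.test_used = "fisher_exact"
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        summary.p_value = float(p)
        summary.test_used = "chi_square"
    return summary


# ---------------------------------------------------------------------------
# variable registry and table construction

Extractor = Callable[[PatientRecord], Optional[float]]


@dataclass(frozen=True)
class RegisteredVariable:
    name: str
    kind: str  # continuous | categorical
    extractor: Extractor


def _lab(name: str) -> Extractor:
    return lambda p: getattr(p.labs, name)


def _sign(name: str) -> Extractor:
    def get(p: PatientRecord):
        v = getattr(p.signs, name)
        return None if v is None else bool(v)
    return get


def default_variable_registry() -> list[RegisteredVariable]:
    """The standard descriptive variable set: demographics, derived age
    indicators, clinical signs, admission labs and derived ratios."""
    reg: list[RegisteredVariable] = [
        RegisteredVariable("male", "categorical",
                           lambda p: None if p.sex == "unknown" else p.sex == "male"),
        RegisteredVariable("age_months", "continuous", lambda p: p.age_months),
        RegisteredVariable("age_lt_1yr", "categorical",
                           lambda p: None if p.age_months is None else p.age_months < 12),
        RegisteredVariable("age_lt_6mo", "categorical",
                           lambda p: None if p.age_months is None else p.age_months < 6),
    ]
    reg += [RegisteredVariable(s, "categorical", _sign(s)) for s in SIGN_FIELDS]
    reg.append(RegisteredVariable("illness_day_at_treatment", "continuous",
                                  lambda p: p.illness_day_at_treatment))
    for lab in ("crp", "alt", "ast", "na", "alb", "plt", "neut_pct", "tb"):
        reg.append(RegisteredVariable(lab, "continuous", _lab(lab)))
    reg.append(RegisteredVariable("nlr", "continuous", lambda p: derive_ratios(p.labs)[0]))
    reg.append(RegisteredVariable("plr", "continuous", lambda p: derive_ratios(p.labs)[1]))
    return reg


@dataclass
class ComparisonTable:
    """Ordered collection of variable summaries with the group sizes."""

    rows: list[VariableSummary]
    group_sizes: dict[str, int]


def build_table2(cohort: Cohort,
                 registry: Optional[Sequence[RegisteredVariable]] = None,
                 denominator_mode: str = "within_group") -> ComparisonTable:
    """Describe a labeled cohort, comparing resistant vs responsive groups.

    Patients with an unknown response label are excluded.  Variables
    whose values are entirely missing in a group are summarized with
    absent statistics rather than raising.
    """
    registry = list(registry) if registry is not None else default_variable_registry()
    groups: dict[str, list[PatientRecord]] = {RESISTANT: [], RESPONSIVE: []}
    for p in cohort:
        if p.ivig_resistant is True:
            groups[RESISTANT].append(p)
        elif p.ivig_resistant is False:
            groups[RESPONSIVE].append(p)
    for g, members in groups.items():
        if not members:
            raise InputError(f"cohort has no patients in the {g!r} group")
    sizes = {g: len(m) for g, m in groups.items()}

    rows = []
    for var in registry:
        if var.kind == "continuous":
            rows.append(summarize_continuous(
                var.name, {g: [var.extractor(p) for p in m] for g, m in groups.items()}))
        else:
            counts, ns = {}, {}
            for g, members in groups.items():
                vals = [var.extractor(p) for p in members]
                known = [v for v in vals if v is not None]
                counts[g] = sum(bool(v) for v in known)
                ns[g] = len(known)
            if min(ns.values()) == 0:
                rows.append(VariableSummary(variable=var.name, kind="categorical",
                                            groups={g: GroupStats(n=0) for g in groups}))
            else:
                rows.append(summarize_categorical(var.name, counts, ns,
                                                  denominator_mode=denominator_mode))
    return ComparisonTable(rows=rows, group_sizes=sizes)


def write_comparison_csv(table: ComparisonTable, target: Union[str, TextIO]) -> None:
    """Export a comparison table as CSV, one row per variable."""

    def _cell(x, fmt="{:.3g}"):
        return "" if x is None else fmt.format(x)

    def _write(fh: TextIO) -> None:
        w = csv.writer(fh)
        w.writerow(["variable", "kind",
                    "resistant_summary", "responsive_summary", "p_value", "test_used"])
        for row in table.rows:
            cells = {}
            for g in (RESISTANT, RESPONSIVE):
                gs = row.groups.get(g)
                if gs is None or (gs.median is None and gs.count is None):
                    cells[g] = ""
                elif row.kind == "continuous":
                    cells[g] = f"{gs.median:.4g} ({gs.q1:.4g}, {gs.q3:.4g})"
                else:
                    cells[g] = f"{gs.count} ({gs.percent:.1f})"
            w.writerow([row.variable, row.kind, cells[RESISTANT], cells[RESPONSIVE],
                        _cell(row.p_value, "{:.4g}"), row.test_used or ""])

    if hasattr(target, "write"):
        _write(target)
    else:
        with open(target, "w", encoding="utf-8", newline="") as fh:
            _write(fh)
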
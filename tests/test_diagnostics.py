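"""Diagnostic accuracy: confusion matrices, metrics, Wilson intervals,
rank AUC against a brute-force oracle, DeLong intervals, rounding."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from kdscore import (ConfusionMatrix, auc_ci_delong, build_report,
                     confusion_from_predictions, diagnostic_metrics, roc_auc,
                     round_report, wilson_interval)
from kdscore.diagnostics import format_proportion, round_half_away
from kdscore.errors import InputError, UndefinedAUCError


# --------------------------------------------------------------------- oracles

def brute_force_auc(scores, labels):
    """Pairwise-comparison AUC: wins + half-ties over all pos/neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_delong_ci(scores, labels, level=0.95):
    """DeLong interval from explicitly looped placement values."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    m, n = len(pos), len(neg)
    v10 = [sum(1.0 if a > b else 0.5 if a == b else 0.0 for b in neg) / n for a in pos]
    v01 = [sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in pos) / m for b in neg]
    auc = sum(v10) / m
    s10 = sum((v - auc) ** 2 for v in v10) / (m - 1)
    s01 = sum((v - auc) ** 2 for v in v01) / (n - 1)
    half = norm.ppf(0.5 + level / 2) * math.sqrt(s10 / m + s01 / n)
    return max(0.0, auc - half), min(1.0, auc + half)


def wilson_closed_form(k, n, level=0.95):
    z = norm.ppf(0.5 + level / 2)
    p = k / n
    center = (p + z * z / (2 * n)) / (1 + z * z / n)
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / (1 + z * z / n)
    return center - half, center + half


# ----------------------------------------------------------------------- tests

class TestConfusionMatrix:
    def test_tally(self):
        cm = confusion_from_predictions([True, True, False, False],
                                        ["high", "low", "high", "low"])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)
        assert cm.n_excluded == 0 and cm.total == 4

    def test_indeterminate_and_unlabeled_excluded(self):
        cm = confusion_from_predictions([True, None, False, False, True],
                                        ["high", "high", "indeterminate", "low", "low"])
        assert cm.n_excluded == 2 and cm.total == 3

    def test_all_responsive_low(self):
        cm = confusion_from_predictions([False] * 7, ["low"] * 7)
        assert cm.tn == 7 and cm.tp == cm.fp == cm.fn == 0

    def test_length_mismatch(self):
        with pytest.raises(InputError, match="length"):
            confusion_from_predictions([True], ["high", "low"])

    def test_negative_count_rejected(self):
        with pytest.raises(InputError):
            ConfusionMatrix(tp=-1)


class TestMetrics:
    def test_reference_style_counts(self):
        m = diagnostic_metrics(ConfusionMatrix(tp=18, fp=120, fn=7, tn=359))
        assert m.sensitivity == Fraction(18, 25)
        assert float(m.specificity) == pytest.approx(0.74947, abs=1e-4)
        assert float(m.ppv) == pytest.approx(0.13043, abs=1e-4)
        assert float(m.npv) == pytest.approx(0.98087, abs=1e-4)

    def test_zero_denominators_undefined(self):
        m = diagnostic_metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
        assert m.sensitivity is None and m.ppv is None
        assert m.specificity == 1 and m.npv == 1

    def test_sensitivity_is_exact_fraction(self):
        m = diagnostic_metrics(ConfusionMatrix(tp=3, fp=0, fn=4, tn=0))
        assert m.sensitivity == Fraction(3, 7)


class TestWilson:
    def test_boundary_cases(self):
        assert wilson_interval(0, 10)[0] == pytest.approx(0.0, abs=1e-12)
        assert wilson_interval(10, 10)[1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k,n", [(18, 25), (5, 48), (436, 456), (1, 504)])
    def test_matches_closed_form(self, k, n):
        lo, hi = wilson_interval(k, n)
        elo, ehi = wilson_closed_form(k, n)
        assert lo == pytest.approx(elo, abs=1e-9)
        assert hi == pytest.approx(ehi, abs=1e-9)
        assert lo <= k / n <= hi

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            wilson_interval(5, 0)
        with pytest.raises(InputError):
            wilson_interval(11, 10)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([3, 4, 1, 2], [True, True, False, False]) == 1.0

    def test_complete_ties(self):
        assert roc_auc([5, 5, 5, 5], [True, False, True, False]) == 0.5

    def test_hand_counted_ties(self):
        # pairs: (2>1), (2=3 -> excluded? no: 2<3 loss), (3>1), (3=3 tie)
        assert roc_auc([2, 3, 1, 3], [True, True, False, False]) == pytest.approx(0.625)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([1, 2], [True, True])

    @settings(deadline=None, max_examples=300)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(2, 12))
        scores = data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if not (any(labels) and not all(labels)):
            labels[0], labels[-1] = True, False
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(tp=st.integers(0, 30), fp=st.integers(0, 30),
           fn=st.integers(0, 30), tn=st.integers(0, 30))
    def test_binary_stratification_equals_balanced_accuracy(self, tp, fp, fn, tn):
        """Scoring high=1/low=0, AUC = (sensitivity + specificity)/2."""
        if tp + fn == 0 or fp + tn == 0:
            tp, tn = tp + 1, tn + 1
        scores = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        labels = [True] * (tp + fn) + [False] * (fp + tn)
        m = diagnostic_metrics(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
        expected = (m.sensitivity + m.specificity) / 2
        assert roc_auc(scores, labels) == pytest.approx(float(expected), abs=1e-12)


class TestDeLong:
    def test_matches_structural_components_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(6, 20))
            scores = rng.integers(0, 4, size=n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                labels[0], labels[-1] = True, False
            got = auc_ci_delong(scores, labels)
            want = brute_force_delong_ci(list(scores), list(labels))
            assert got == pytest.approx(want, abs=1e-10)

    def test_perfect_separation_collapses(self):
        scores = [1.0] * 100 + [0.0] * 100
        labels = [True] * 100 + [False] * 100
        lo, hi = auc_ci_delong(scores, labels)
        assert lo == pytest.approx(1.0) and hi == 1.0

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=200) + np.repeat([1.0, 0.0], 100)
        labels = np.repeat([True, False], 100)
        lo, hi = auc_ci_delong(scores, labels)
        assert lo <= roc_auc(scores, labels) <= hi


class TestRounding:
    @pytest.mark.parametrize("num,den,dp,expected", [
        (18, 25, 2, "0.72"),
        (295, 479, 2, "0.62"),
        (359, 479, 2, "0.75"),
        (267, 278, 2, "0.96"),
    ])
    def test_exact_ratio_rounding(self, num, den, dp, expected):
        assert format_proportion(Fraction(num, den), dp) == expected

    def test_half_away_from_zero(self):
        assert str(round_half_away(0.5, 0)) == "1"
        assert str(round_half_away(Fraction(1, 8), 2)) == "0.13"  # 0.125 rounds up
        assert str(round_half_away(Fraction(-1, 8), 2)) == "-0.13"

    def test_undefined_prints_placeholder(self):
        assert format_proportion(None) == "--"

    def test_round_report_shape(self):
        rep = build_report("demo", ConfusionMatrix(tp=18, fp=120, fn=7, tn=359),
                           scores=[1, 1, 0, 0], labels=[True, True, False, False])
        row = round_report(rep)
        assert row["sensitivity"] == "0.72" and row["specificity"] == "0.75"
        assert row["auc"] == "1.00"
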
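"""Scoring engine: registry contents, boundary semantics, missing-data
policies, and score monotonicity."""

import numpy as np
import pytest

from kdscore import (CombinationRuleModel, LabPanel, ScoreCriterion,
                     apply_kawamura, apply_point_model, builtin_models,
                     evaluate_criterion, score_patient)
from kdscore.errors import ConfigurationError
from kdscore.scoring import EITHER_SUFFICIENT, HIGH, INDETERMINATE, LOW, MET, MISSING, UNMET
from conftest import make_patient

MAX_POINTS = {"kobayashi": 11, "egami": 6, "sano": 3, "formosa": 4, "ours": 7}


class TestRegistry:
    def test_six_models(self, models):
        assert set(models) == {"kobayashi", "egami", "sano", "formosa", "ours", "kawamura"}

    @pytest.mark.parametrize("name,max_points", sorted(MAX_POINTS.items()))
    def test_max_attainable_scores(self, models, name, max_points):
        assert models[name].max_points == max_points

    def test_cutoffs(self, models):
        assert models["sano"].high_risk_cutoff == 2
        assert len(models["sano"].criteria) == 3
        for name in ("kobayashi", "egami", "formosa", "ours"):
            assert models[name].high_risk_cutoff == 3

    def test_kobayashi_original_cutoff_selectable(self):
        assert builtin_models(kobayashi_cutoff=4)["kobayashi"].high_risk_cutoff == 4

    def test_duplicate_variables_rejected(self):
        from kdscore.scoring import RiskScoreModel
        c = ScoreCriterion("crp", ">=", 100.0, 1)
        with pytest.raises(ConfigurationError, match="distinct"):
            RiskScoreModel("bad", (c, c), 1)

    def test_unknown_variable_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown variable"):
            ScoreCriterion("ferritin", ">=", 500.0, 1)


class TestBoundarySemantics:
    """Inclusive ≥/≤ vs strict >/< exactly as the published tables print them."""

    def test_crp_at_100_met_for_kobayashi(self, models):
        p = make_patient(crp=100.0)
        crit = next(c for c in models["kobayashi"].criteria if c.variable == "crp")
        assert evaluate_criterion(crit, p) == MET

    def test_plt_300_inclusive_kobayashi_strict_egami(self, models):
        p = make_patient(plt=300.0)
        kob = next(c for c in models["kobayashi"].criteria if c.variable == "plt")
        ega = next(c for c in models["egami"].criteria if c.variable == "plt")
        assert evaluate_criterion(kob, p) == MET     # PLT ≤ 300
        assert evaluate_criterion(ega, p) == UNMET   # PLT < 300

    def test_age_6_months_strict_ours_inclusive_egami(self, models):
        p = make_patient(age_months=6.0)
        ours = next(c for c in models["ours"].criteria if c.variable == "age_months")
        ega = next(c for c in models["egami"].criteria if c.variable == "age_months")
        assert evaluate_criterion(ours, p) == UNMET  # age < 6
        assert evaluate_criterion(ega, p) == MET     # age ≤ 6

    def test_fractional_age_below_boundary(self, models):
        crit = next(c for c in models["ours"].criteria if c.variable == "age_months")
        assert evaluate_criterion(crit, make_patient(age_months=5.9)) == MET

    def test_missing_lab_is_missing(self, models):
        crit = next(c for c in models["sano"].criteria if c.variable == "tb")
        assert evaluate_criterion(crit, make_patient()) == MISSING


class TestPointModels:
    def test_ours_young_low_albumin(self, models):
        p = make_patient(age_months=5, alb=34.0, neut_pct=50.0,
                         signs={"rash": False, "edema_extremities": False})
        r = apply_point_model(models["ours"], p)
        assert r.total_points == 4 and r.risk_class == HIGH

    def test_ours_inclusive_npct_boundary(self, models):
        p = make_patient(age_months=20, alb=38.0, neut_pct=80.0,
                         signs={"rash": True, "edema_extremities": True})
        r = apply_point_model(models["ours"], p)
        assert r.total_points == 3 and r.risk_class == HIGH

    def test_kobayashi_all_criteria_met(self, models):
        p = make_patient(age_months=10, illness_day=3, crp=150.0, ast=120.0,
                         plt=250.0, na=130.0, neut_pct=85.0)
        r = apply_point_model(models["kobayashi"], p)
        assert r.total_points == 11 and r.risk_class == HIGH

    def test_sano_all_normal(self, models):
        p = make_patient(crp=20.0, tb=5.0, ast=30.0)
        r = apply_point_model(models["sano"], p)
        assert r.total_points == 0 and r.risk_class == LOW

    def test_indeterminate_only_when_outcome_could_change(self, models):
        # ours: 2+2 met already reaches the cutoff -> high despite missing rash
        p = make_patient(age_months=5, alb=34.0, neut_pct=50.0,
                         signs={"edema_extremities": False})
        assert apply_point_model(models["ours"], p).risk_class == HIGH
        # 0 met, missing alb (2 pts) + rash (1 pt) could reach 3 -> indeterminate
        q = make_patient(age_months=20, neut_pct=50.0,
                         signs={"edema_extremities": False})
        r = apply_point_model(models["ours"], q)
        assert r.risk_class == INDETERMINATE
        assert set(r.missing_variables) == {"alb", "rash"}
        # missing criteria cannot reach the cutoff -> low
        s = make_patient(age_months=20, alb=40.0, neut_pct=50.0,
                         signs={"edema_extremities": False})
        assert apply_point_model(models["ours"], s).risk_class == LOW

    def test_treat_as_unmet_never_indeterminate(self):
        models = builtin_models(missing_policy="treat_as_unmet")
        blank = make_patient(age_months=None, illness_day=None)
        for name, model in models.items():
            assert score_patient(model, blank).risk_class in (HIGH, LOW)


class TestKawamura:
    def test_inclusive_boundaries_high(self):
        p = make_patient(neut_count=3.83, lymph_count=1.0, plt=150.0)
        assert apply_kawamura(p).risk_class == HIGH

    def test_one_predictor_low_unless_either_sufficient(self):
        p = make_patient(neut_count=5.0, lymph_count=1.0, plt=100.0)  # NLR 5, PLR 100
        assert apply_kawamura(p).risk_class == LOW
        rule = CombinationRuleModel(combination=EITHER_SUFFICIENT)
        assert apply_kawamura(p, rule).risk_class == HIGH

    def test_missing_lymphocytes_indeterminate(self):
        p = make_patient(neut_count=5.0, plt=100.0)
        r = apply_kawamura(p)
        assert r.risk_class == INDETERMINATE
        assert set(r.missing_variables) == {"nlr", "plr"}

    def test_partial_missing_settled_by_observed_ratio(self):
        # PLR observed below threshold settles both_required as low
        p = make_patient(lymph_count=2.0, plt=100.0)  # PLR 50, NLR missing
        assert apply_kawamura(p).risk_class == LOW

    def test_ordinal_score_counts_satisfied(self):
        p = make_patient(neut_count=10.0, lymph_count=1.0, plt=400.0)
        r = apply_kawamura(p)
        assert r.total_points is None and r.ordinal_score == 2


def _risk_direction(comparator):
    return -1 if comparator in ("<=", "<") else +1


def _random_patient(rng):
    return make_patient(
        age_months=float(rng.uniform(0, 60)),
        illness_day=int(rng.integers(1, 12)),
        signs={"rash": bool(rng.random() < 0.5),
               "edema_extremities": bool(rng.random() < 0.5),
               "cervical_lymphadenopathy": bool(rng.random() < 0.5)},
        crp=float(rng.uniform(1, 250)), alt=float(rng.uniform(5, 300)),
        ast=float(rng.uniform(5, 300)), na=float(rng.uniform(125, 145)),
        alb=float(rng.uniform(25, 50)), plt=float(rng.uniform(100, 700)),
        neut_pct=float(rng.uniform(20, 99)), tb=float(rng.uniform(1, 40)),
    )


class TestProperties:
    def test_monotone_in_risk_direction(self, models):
        """Moving any one numeric input toward higher risk never lowers
        the total score (random patients × random perturbations).

        Criterion variables are distinct within a model, so a
        perturbation aimed at one criterion cannot un-meet another.
        """
        import copy

        rng = np.random.default_rng(2024)
        point_models = [m for n, m in sorted(models.items()) if n != "kawamura"]
        for _ in range(500):
            p = _random_patient(rng)
            for model in point_models:
                base = apply_point_model(model, p).total_points
                for crit in model.criteria:
                    if crit.comparator == "is_present":
                        continue
                    q = copy.deepcopy(p)
                    delta = float(rng.uniform(0, 50)) * _risk_direction(crit.comparator)
                    if crit.variable == "age_months":
                        q.age_months = max(0.0, q.age_months + delta)
                    elif crit.variable == "illness_day_at_treatment":
                        q.illness_day_at_treatment = max(
                            1, q.illness_day_at_treatment + int(delta))
                    else:
                        cur = getattr(q.labs, crit.variable)
                        new = max(0.0, cur + delta)
                        if crit.variable == "neut_pct":
                            new = min(100.0, new)
                        setattr(q.labs, crit.variable, new)
                    assert apply_point_model(model, q).total_points >= base

    def test_determinism_and_bounds(self, models, small_cohort):
        for p in small_cohort[:100]:
            for name, model in models.items():
                r1, r2 = score_patient(model, p), score_patient(model, p)
                assert r1 == r2
                if r1.total_points is not None:
                    assert 0 <= r1.total_points <= MAX_POINTS[name]
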
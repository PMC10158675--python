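import numpy as np
import pandas as pd
import pytest

from modsew.counterfactuals import (
    CFError,
    CFQuery,
    default_rules,
    diversity,
    generate,
    mad_scales,
    proximity,
    repair,
    report_frame,
    rule_screen,
)
from modsew.features import CURRENT_SCORE_FEATURE, FEATURE_NAMES, ROLLING_SCORE_FEATURE
from modsew.learners import LearnerSpec, class_weights, fit
from modsew.scoring import ORGANS


@pytest.fixture(scope="module")
def cohort_model(small_entries, feature_names):
    X = small_entries[feature_names].to_numpy(float)
    y = small_entries["label"].to_numpy(int)
    handle = fit(LearnerSpec("logistic_regression", seed=0), X, y, weights=class_weights(y))
    return handle, small_entries


@pytest.fixture(scope="module")
def positive_instance(cohort_model, feature_names):
    handle, entries = cohort_model
    probs = handle.predict_proba(entries[feature_names].to_numpy(float))
    i = int(np.argmax(probs))
    return entries.iloc[i][feature_names].astype(float)


@pytest.fixture(scope="module")
def scales(cohort_model, feature_names):
    return mad_scales(cohort_model[1][feature_names])


def _uniform_scales():
    return pd.Series(1.0, index=list(FEATURE_NAMES))


class TestProximity:
    def test_identity_is_zero(self, positive_instance):
        assert proximity(positive_instance, positive_instance, _uniform_scales()) == 0.0

    def test_symmetric(self, positive_instance):
        cf = positive_instance.copy()
        cf["currentMaxHr"] += 7.0
        s = _uniform_scales()
        assert proximity(positive_instance, cf, s) == proximity(cf, positive_instance, s)

    def test_two_features_one_mad_each(self, positive_instance):
        s = _uniform_scales()
        s["currentMaxHr"] = 4.0
        s["currentMaxLactate"] = 0.5
        cf = positive_instance.copy()
        cf["currentMaxHr"] += 4.0
        cf["currentMaxLactate"] -= 0.5
        assert proximity(positive_instance, cf, s) == pytest.approx(2.0)

    def test_feature_mismatch_errors(self, positive_instance):
        with pytest.raises(CFError):
            proximity(positive_instance, positive_instance.drop("currentHour"),
                      _uniform_scales(), ["currentHour"])


class TestDiversity:
    def test_single_candidate_det_one(self, positive_instance):
        assert diversity([positive_instance], _uniform_scales()) == pytest.approx(1.0)

    def test_duplicate_det_zero(self, positive_instance):
        d = diversity([positive_instance, positive_instance.copy()], _uniform_scales())
        assert d == pytest.approx(0.0)

    def test_proximity_one_pair(self, positive_instance):
        cf = positive_instance.copy()
        cf["currentMaxHr"] += 1.0
        d = diversity([positive_instance, cf], _uniform_scales())
        assert d == pytest.approx(1 - 0.25)

    def test_empty_rejected(self):
        with pytest.raises(CFError):
            diversity([], _uniform_scales())


class TestRuleScreen:
    def test_inconsistent_gcs_score_dropped(self, positive_instance, table):
        cand = positive_instance.copy()
        cand["currentMinGcs"] = 5.0  # maps to sub-score 4
        cand["currentMeanGcs"] = 5.0
        cand["currentMaxGcs"] = 5.0
        cand[CURRENT_SCORE_FEATURE["neurologic"]] = 2.0
        assert rule_screen([cand], table=table) == []

    def test_rolling_below_current_dropped(self, positive_instance, table):
        cand = repair(positive_instance, table)
        cand[ROLLING_SCORE_FEATURE["neurologic"]] = cand[CURRENT_SCORE_FEATURE["neurologic"]] - 1
        assert rule_screen([cand], table=table) == []

    def test_min_above_max_dropped(self, positive_instance, table):
        cand = repair(positive_instance, table)
        cand["currentMinHr"] = cand["currentMaxHr"] + 10
        assert rule_screen([cand], table=table) == []

    def test_consistent_candidates_unchanged(self, positive_instance, table):
        cand = repair(positive_instance, table)
        out = rule_screen([cand, cand.copy()], table=table)
        assert len(out) == 2

    def test_repair_soundness(self, positive_instance, table):
        from modsew.counterfactuals import ORGAN_AGGREGATE_FEATURES
        from modsew.scoring import score_variable

        cand = positive_instance.copy()
        cand["currentMinGcs"] = 5.0
        fixed = repair(cand, table)
        for organ in ORGANS:
            derived = max(
                score_variable(float(fixed[f]), var, table)
                for f, var in ORGAN_AGGREGATE_FEATURES[organ]
            )
            assert fixed[CURRENT_SCORE_FEATURE[organ]] == derived
            assert fixed[ROLLING_SCORE_FEATURE[organ]] >= fixed[CURRENT_SCORE_FEATURE[organ]]


class TestGenerate:
    def _model_fn(self, handle):
        return lambda X: handle.predict_proba(np.asarray(X, dtype=float))

    def test_candidates_flip_prediction(self, cohort_model, positive_instance, scales, table):
        handle, _ = cohort_model
        q = CFQuery(instance=positive_instance, k=3, seed=4, budget=1500)
        out = generate(self._model_fn(handle), q, table=table, scales=scales)
        assert len(out) >= 1
        for cand in out.candidates:
            assert cand.probability < 0.5

    def test_immutable_current_hour_unchanged(self, cohort_model, positive_instance, scales, table):
        handle, _ = cohort_model
        q = CFQuery(instance=positive_instance, k=3, seed=4, budget=1500)
        out = generate(self._model_fn(handle), q, table=table, scales=scales)
        for cand in out.candidates:
            assert cand.features["currentHour"] == positive_instance["currentHour"]

    def test_k3_distinct_changed_sets(self, cohort_model, positive_instance, scales, table):
        handle, _ = cohort_model
        q = CFQuery(instance=positive_instance, k=3, seed=4, budget=2000, lambda_diversity=1.0)
        out = generate(self._model_fn(handle), q, table=table, scales=scales)
        sets = [frozenset(c.changed_features) for c in out.candidates]
        assert len(sets) == len(set(sets))

    def test_candidates_pass_rule_screen(self, cohort_model, positive_instance, scales, table):
        handle, _ = cohort_model
        q = CFQuery(instance=positive_instance, k=3, seed=7, budget=1500)
        out = generate(self._model_fn(handle), q, table=table, scales=scales)
        screened = rule_screen([c.features for c in out.candidates], table=table)
        assert len(screened) == len(out.candidates)

    def test_pair_diversity_positive(self, cohort_model, positive_instance, scales, table):
        handle, _ = cohort_model
        q = CFQuery(instance=positive_instance, k=2, seed=5, budget=2000, lambda_diversity=1.0)
        out = generate(self._model_fn(handle), q, table=table, scales=scales)
        if len(out) == 2:
            assert out.diversity_score > 0.0  # duplicated candidate would give 0

    def test_already_negative_instance_rejected(self, cohort_model, feature_names, table):
        handle, entries = cohort_model
        probs = handle.predict_proba(entries[feature_names].to_numpy(float))
        i = int(np.argmin(probs))
        inst = entries.iloc[i][feature_names].astype(float)
        with pytest.raises(CFError):
            generate(self._model_fn(handle), CFQuery(instance=inst, seed=1), table=table)

    def test_act_before_hour_reported(self, cohort_model, positive_instance, scales, table):
        handle, _ = cohort_model
        q = CFQuery(instance=positive_instance, k=1, seed=4, budget=800)
        out = generate(self._model_fn(handle), q, table=table, scales=scales, horizon=12)
        assert out.act_before_hour == positive_instance["currentHour"] + 12

    def test_report_frame_columns(self, cohort_model, positive_instance, scales, table):
        handle, _ = cohort_model
        q = CFQuery(instance=positive_instance, k=2, seed=4, budget=1000)
        out = generate(self._model_fn(handle), q, table=table, scales=scales)
        frame = report_frame(out, positive_instance)
        assert list(frame.columns) == ["candidate", "feature", "old", "new", "probability", "proximity"]

    def test_query_validation(self, positive_instance):
        with pytest.raises(CFError):
            CFQuery(instance=positive_instance, k=0)
        with pytest.raises(CFError):
            CFQuery(instance=positive_instance.drop("currentHour"))
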
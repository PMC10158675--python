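import numpy as np
import pandas as pd
import pytest

from modsew.features import (
    CURRENT_SCORE_FEATURE,
    ENTRY_COLUMNS,
    FEATURE_NAMES,
    ROLLING_SCORE_FEATURE,
    CohortFilter,
    FeatureError,
    apply_normalizer,
    build_entries,
    extract_features,
    featurize_stay,
    filter_cohort,
    fit_normalizer,
    hourly_frame,
    impute_clinical,
    label_entries,
    missing_rate,
    read_entries,
    split_by_patient,
    write_entries,
)
from modsew.scoring import ORGANS, VARIABLES
from modsew.synthetic import Observation, PatientStay, SimConfig, simulate_cohort


def _stay(pid="P1", age=70.0, first=True, hours=30, variables=VARIABLES, onset=None):
    rng = np.random.default_rng(3)
    obs = []
    healthy = {
        "heart_rate": 80, "dopamine": 0, "oxygenation_index": 400, "gcs": 15,
        "lactate": 1.0, "creatinine": 80, "bilirubin": 10, "platelets": 250,
    }
    for var in variables:
        for h in range(hours):
            obs.append(Observation(h + 0.5, var, float(healthy[var])))
    return PatientStay(pid, age, first, sorted(obs, key=lambda o: o.time_offset), onset)


class TestFilterCohort:
    def test_age_exclusion(self):
        kept, log = filter_cohort([_stay(age=64.0)])
        assert kept == [] and log == [("P1", "age")]

    def test_age_65_included(self):
        kept, _ = filter_cohort([_stay(age=65.0)])
        assert len(kept) == 1

    def test_los_exclusion(self):
        kept, log = filter_cohort([_stay(hours=20)])
        assert log == [("P1", "length_of_stay")]

    def test_missingness_exclusion(self):
        stay = _stay(variables=VARIABLES[:5])  # 3/8 = 0.375 missing
        kept, log = filter_cohort([stay])
        assert log == [("P1", "missingness")]

    def test_not_first_stay_exclusion(self):
        kept, log = filter_cohort([_stay(first=False)])
        assert log == [("P1", "not_first_stay")]

    def test_one_reason_per_excluded_stay(self):
        stays = [_stay(pid=f"P{i}", age=60.0, hours=10) for i in range(3)]
        kept, log = filter_cohort(stays)
        assert len(log) == 3
        assert all(reason == "age" for _, reason in log)

    def test_missing_rate_modes(self):
        stay = _stay(variables=VARIABLES[:6])
        assert missing_rate(stay, "variable") == pytest.approx(0.25)
        assert 0 <= missing_rate(stay, "hourly") <= 1


class TestImputeClinical:
    def test_leading_and_trailing_gaps(self):
        filled, flagged = impute_clinical([np.nan, 7.0, np.nan])
        assert filled.tolist() == [7.0, 7.0, 7.0] and not flagged

    def test_forward_precedence(self):
        filled, _ = impute_clinical([1.0, np.nan, 3.0])
        assert filled.tolist() == [1.0, 1.0, 3.0]

    def test_all_gap_flagged(self):
        filled, flagged = impute_clinical([np.nan, np.nan])
        assert flagged and np.isnan(filled).all()


class TestExtractFeatures:
    def test_feature_count_is_37(self):
        fv = extract_features(_stay(), 5)
        assert len(fv) == 37
        assert list(fv.index) == list(FEATURE_NAMES)

    def test_constant_window_mean_max_min_equal(self):
        fv = extract_features(_stay(), 3)
        for var, tok in [("creatinine", "Creatinine"), ("gcs", "Gcs")]:
            assert fv[f"currentMean{tok}"] == fv[f"currentMax{tok}"] == fv[f"currentMin{tok}"]

    def test_hour_one_rolling_equals_current(self):
        fv = extract_features(_stay(), 1)
        for organ in ORGANS:
            assert fv[ROLLING_SCORE_FEATURE[organ]] == fv[CURRENT_SCORE_FEATURE[organ]]

    def test_min_le_mean_le_max(self, small_cohort):
        cohort, _ = small_cohort
        frame = hourly_frame(cohort[0])
        for var in VARIABLES:
            assert (frame[f"min_{var}"] <= frame[f"mean_{var}"] + 1e-12).all()
            assert (frame[f"mean_{var}"] <= frame[f"max_{var}"] + 1e-12).all()

    def test_out_of_range_hour_errors(self):
        with pytest.raises(FeatureError):
            extract_features(_stay(hours=10), 99)

    def test_rolling_is_trailing_max_oracle(self):
        # pandas rolling vs brute force on 1000 random score sequences
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            scores = rng.integers(0, 5, size=n)
            rolled = (
                pd.Series(scores).rolling(24, min_periods=1).max().to_numpy()
            )
            brute = np.array([scores[max(0, i - 23) : i + 1].max() for i in range(n)])
            assert (rolled == brute).all()

    def test_rolling_ge_current_on_real_stays(self, small_cohort):
        cohort, _ = small_cohort
        for stay in cohort[:5]:
            frame = hourly_frame(stay)
            for organ in ORGANS:
                assert (frame[f"rolling_{organ}"] >= frame[f"score_{organ}"]).all()


class TestLabelEntries:
    def test_positive_12h_before_onset(self):
        labels = label_entries(100, onset=72)
        assert labels[60] == 1

    def test_no_onset_all_zero(self):
        labels = label_entries(240, onset=None)
        assert labels.sum() == 0

    def test_outside_horizon_negative(self):
        labels = label_entries(100, onset=100)
        assert labels[60] == 0 and labels[88] == 1

    def test_earliest_positive_is_onset_minus_horizon(self, small_cohort):
        cohort, truth = small_cohort
        for stay in cohort:
            onset = truth[stay.patient_id]
            if onset is None:
                continue
            labels = label_entries(stay.length_hours, onset)
            first_pos = labels[labels == 1].index.min()
            assert first_pos == max(1, onset - 12)

    def test_post_onset_hours_positive(self):
        labels = label_entries(50, onset=20)
        assert (labels.loc[20:] == 1).all()

    def test_truncate_at_onset(self):
        labels = label_entries(50, onset=20, truncate_at_onset=True)
        assert labels.index.max() == 20

    def test_bad_horizon(self):
        with pytest.raises(FeatureError):
            label_entries(10, onset=None, horizon=0)


class TestNormalizer:
    def test_self_normalization_identity(self, small_entries):
        params = fit_normalizer(small_entries)
        normed = apply_normalizer(small_entries, params)
        X = normed[list(FEATURE_NAMES)]
        varying = params.sigma[params.sigma > 0].index
        assert np.allclose(X[varying].mean(), 0.0, atol=1e-9)
        assert np.allclose(X[varying].std(ddof=0), 1.0, atol=1e-9)

    def test_sigma_zero_centers_only(self):
        df = pd.DataFrame({name: [1.0, 1.0, 1.0] for name in FEATURE_NAMES})
        params = fit_normalizer(df)
        out = apply_normalizer(df, params)
        assert (out[list(FEATURE_NAMES)] == 0.0).all().all()

    def test_shifted_test_set_closed_form(self, small_entries):
        params = fit_normalizer(small_entries)
        c = 3.0
        shifted = small_entries.copy()
        shifted[list(FEATURE_NAMES)] = shifted[list(FEATURE_NAMES)] + c
        out = apply_normalizer(shifted, params)
        varying = params.sigma[params.sigma > 0].index
        expected = c / params.sigma[varying]
        assert np.allclose(out[varying].mean(), expected, atol=1e-9)

    def test_feature_mismatch_errors(self, small_entries):
        params = fit_normalizer(small_entries)
        with pytest.raises(FeatureError):
            apply_normalizer(small_entries.drop(columns=["currentHour"]), params)

    def test_json_round_trip(self, tmp_path, small_entries):
        from modsew.features import NormalizationParams

        params = fit_normalizer(small_entries)
        p = tmp_path / "norm.json"
        params.to_json(p)
        back = NormalizationParams.from_json(p)
        assert np.allclose(back.mu[list(FEATURE_NAMES)], params.mu[list(FEATURE_NAMES)])
        assert np.allclose(back.sigma[list(FEATURE_NAMES)], params.sigma[list(FEATURE_NAMES)])


class TestSplitByPatient:
    def _entries(self, n_patients=10):
        rows = []
        for i in range(n_patients):
            for h in range(1, 4):
                rows.append({"patient_id": f"P{i}", "hour": h, "label": i % 2})
        return pd.DataFrame(rows)

    def test_counts_10_patients(self):
        train, val = split_by_patient(self._entries(), 0.8, seed=1)
        assert train["patient_id"].nunique() == 8
        assert val["patient_id"].nunique() == 2

    def test_determinism(self):
        a = split_by_patient(self._entries(), 0.8, seed=5)
        b = split_by_patient(self._entries(), 0.8, seed=5)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_no_leakage(self):
        train, val = split_by_patient(self._entries(), 0.8, seed=2)
        assert not (set(train["patient_id"]) & set(val["patient_id"]))

    def test_stratified_keeps_both_classes(self):
        train, val = split_by_patient(self._entries(20), 0.8, seed=3, stratify_onsets=True)
        assert val.groupby("patient_id")["label"].max().nunique() == 2

    def test_too_few_patients(self):
        with pytest.raises(FeatureError):
            split_by_patient(self._entries(1))


class TestEntriesTable:
    def test_schema(self, small_entries):
        assert list(small_entries.columns) == list(ENTRY_COLUMNS)
        assert set(small_entries["label"].unique()) <= {0, 1}

    def test_csv_round_trip(self, tmp_path, small_entries):
        p = tmp_path / "entries.csv"
        write_entries(small_entries, p)
        back = read_entries(p)
        assert np.allclose(
            back[list(FEATURE_NAMES)].to_numpy(),
            small_entries[list(FEATURE_NAMES)].to_numpy(),
        )

    def test_featurize_stay_label_alignment(self, small_cohort):
        cohort, truth = small_cohort
        stay = next(s for s in cohort if truth[s.patient_id] is not None)
        onset = truth[stay.patient_id]
        entries = featurize_stay(stay, onset)
        positives = entries[entries["label"] == 1]["hour"]
        assert positives.min() == max(1, onset - 12)

    def test_empty_cohort(self):
        out = build_entries([], {})
        assert len(out) == 0 and list(out.columns) == list(ENTRY_COLUMNS)
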
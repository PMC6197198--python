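"""Encoding, balancing, forest training and the evaluation protocols."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from phenodose import (
    AnalysisConfig,
    balance,
    check_eligibility,
    cross_validate_10fold,
    encode_matrix,
    holdout_last_year,
    train_rf,
)
from phenodose.classify import split_features_per_tree
from phenodose.profiles import PhenotypeProfile


def _profile(n_features):
    stats = pd.DataFrame({
        "feature_type": ["lab"] * n_features,
        "feature_id": [f"L{i:03d}" for i in range(n_features)],
        "a": 1, "b": 1, "c": 1, "d": 1,
        "p_value": 1e-6, "rr": 4.0, "ic": 5.0,
        "direction": "positive",
        "display_label": [f"L{i:03d}" for i in range(n_features)],
    })
    return PhenotypeProfile("s", "reduction", stats, bonferroni_m=10)


class TestEligibility:
    def test_too_few_cases(self):
        ok, reason = check_eligibility(149, 10_000, _profile(3), 1000)
        assert not ok and reason == "min case count"

    def test_empty_profile(self):
        ok, reason = check_eligibility(300, 300, _profile(0), 1000)
        assert not ok and reason == "empty profile"

    def test_prescription_volume_cap(self):
        ok, reason = check_eligibility(300, 300, _profile(3), 56_000)
        assert not ok and reason == "prescription volume cap"

    def test_eligible_subject(self):
        ok, reason = check_eligibility(300, 300, _profile(3), 54_000)
        assert ok and reason == "eligible"


class TestEncoding:
    def test_matrix_has_exactly_profile_columns(self):
        fs = pd.DataFrame(
            [("i1", "lab", "L000"), ("i2", "lab", "L001")],
            columns=["interval_id", "feature_type", "feature_id"],
        )
        feats = [("lab", f"L{i:03d}") for i in range(300)]
        X = encode_matrix(["i1", "i2", "i3"], feats, fs)
        assert X.shape == (3, 300)
        assert X.loc["i1", "lab:L000"] == 1 and X.loc["i3"].sum() == 0

    def test_row_order_invariance(self):
        fs = pd.DataFrame(
            [("i1", "lab", "A"), ("i2", "lab", "B")],
            columns=["interval_id", "feature_type", "feature_id"],
        )
        feats = [("lab", "A"), ("lab", "B")]
        X1 = encode_matrix(["i1", "i2"], feats, fs)
        X2 = encode_matrix(["i2", "i1"], feats, fs).loc[["i1", "i2"]]
        pd.testing.assert_frame_equal(X1, X2)

    def test_unknown_profile_feature_is_fatal(self):
        fs = pd.DataFrame(
            [("i1", "lab", "A")],
            columns=["interval_id", "feature_type", "feature_id"],
        )
        with pytest.raises(ValueError, match="universe"):
            encode_matrix(["i1"], [("lab", "GHOST")], fs,
                          universe={("lab", "A")})


class TestBalance:
    def test_undersamples_majority(self):
        ids = [f"c{i}" for i in range(400)] + [f"t{i}" for i in range(1000)]
        y = [1] * 400 + [0] * 1000
        kept = balance(ids, y, seed=0)
        kept_y = [1 if i.startswith("c") else 0 for i in kept]
        assert sum(kept_y) == 400 and len(kept) == 800

    def test_already_balanced_keeps_everything(self):
        ids = ["a", "b", "c", "d"]
        kept = balance(ids, [1, 1, 0, 0], seed=0)
        assert sorted(kept) == sorted(ids)

    def test_seeded_determinism(self):
        ids = [f"x{i}" for i in range(100)]
        y = [1] * 30 + [0] * 70
        assert balance(ids, y, seed=5) == balance(ids, y, seed=5)

    def test_empty_class_is_fatal(self):
        with pytest.raises(ValueError, match="class is empty"):
            balance(["a"], [1], seed=0)


class TestForest:
    @pytest.mark.parametrize("m, expected", [(300, 9), (1, 1), (2, 2), (64, 7)])
    def test_split_candidates_rule(self, m, expected):
        assert split_features_per_tree(m) == expected

    def test_zero_features_is_fatal(self):
        with pytest.raises(ValueError):
            split_features_per_tree(0)

    def test_perfectly_predictive_feature_separates_training_set(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 50 + [0] * 50)
        X = pd.DataFrame({
            "lab:PERFECT": y,
            "lab:NOISE": rng.integers(0, 2, 100),
        })
        model = train_rf(X, y, seed=0)
        scores = model.predict_proba(X.to_numpy())[:, 1]
        assert roc_auc_score(y, scores) == pytest.approx(1.0)
        assert model.get_params()["max_features"] == 2  # int(log2(2)+1)


@pytest.fixture(scope="module")
def study(small_study):
    cohort, intervals, feature_sets, acfg = small_study
    sub = intervals[intervals["label"].isin(["reduction", "continuation"])]
    return cohort, sub, feature_sets, acfg


class TestEvaluationProtocols:
    def test_cv_runs_with_per_fold_profiles(self, study):
        cohort, intervals, feature_sets, acfg = study
        res = cross_validate_10fold(
            intervals, feature_sets, cohort.ontologies, acfg, seed=0,
            subject="DRUG_A",
        )
        assert len(res.per_fold["auc_roc"]) == acfg.n_folds
        assert 0.0 <= res.auc_roc <= 1.0
        assert len(res.fold_features) == acfg.n_folds
        # balanced-before: every fold trains on (k-1)/k of the balanced set
        assert res.n_instances == pytest.approx(
            9 / 10 * (2 * min(
                (intervals["label"] == "reduction").sum(),
                (intervals["label"] == "continuation").sum(),
            )), rel=0.02,
        )
        p, r = res.precision, res.recall
        assert res.f_measure == pytest.approx(2 * p * r / (p + r))

    def test_no_test_interval_enters_its_own_folds_profile_counts(self, study):
        cohort, intervals, feature_sets, acfg = study
        res = cross_validate_10fold(
            intervals, feature_sets, cohort.ontologies, acfg, seed=1,
        )
        universe = set.union(*res.fold_train_ids)
        for train_ids in res.fold_train_ids:
            test_ids = universe - train_ids
            assert test_ids and not (test_ids & train_ids)
        # each interval is held out exactly once across the k folds
        holdout_counts = {}
        for train_ids in res.fold_train_ids:
            for iid in universe - train_ids:
                holdout_counts[iid] = holdout_counts.get(iid, 0) + 1
        assert set(holdout_counts.values()) == {1}

    def test_holdout_trains_strictly_before_cutoff(self, study):
        cohort, intervals, feature_sets, acfg = study
        res = holdout_last_year(
            intervals, feature_sets, cohort.ontologies, acfg, seed=0,
        )
        years = dict(zip(intervals["interval_id"],
                         pd.DatetimeIndex(intervals["t1"]).year))
        assert all(years[i] < acfg.holdout_year for i in res.fold_train_ids[0])
        if res.skipped_reason is None:
            assert 0.0 <= res.auc_roc <= 1.0

    def test_holdout_with_everything_in_cutoff_year_is_fatal(self, study):
        cohort, intervals, feature_sets, acfg = study
        shifted = intervals.copy()
        shifted["t1"] = pd.Timestamp("2014-06-01")
        with pytest.raises(ValueError, match="empty training or test side"):
            holdout_last_year(shifted, feature_sets, cohort.ontologies, acfg)

    def test_five_strong_features_reach_near_bayes_auc(self):
        """Five planted features at prevalence 0.30 vs 0.05 (RR 6) carry a
        Bayes-optimal AUC of 0.848; the cross-validated forest should land
        within a small slack of that information bound."""
        from phenodose.simulate import (PlantedFeature, SimulationConfig,
                                        simulate_cohort)
        from phenodose.studies import prepare_study

        planted = tuple(
            PlantedFeature(t, 0.30, 0.05)
            for t in ("diagnosis", "diagnosis", "condition", "condition", "lab")
        )
        cfg = SimulationConfig(n_patients=3000, p_reduction=0.4,
                               p_increase=0.2, planted_features=planted,
                               seed=21)
        cohort = simulate_cohort(cfg)
        acfg = AnalysisConfig()
        intervals, feature_sets = prepare_study(cohort, acfg)
        sub = intervals[intervals["label"].isin(["reduction", "continuation"])]
        res = cross_validate_10fold(sub, feature_sets, cohort.ontologies,
                                    acfg, seed=21)
        assert 0.78 <= res.auc_roc <= 0.86

    def test_label_permutation_drives_auc_to_chance(self, study):
        cohort, intervals, feature_sets, acfg = study
        rng = np.random.default_rng(2)
        perm = intervals.copy()
        perm["label"] = rng.permutation(perm["label"].to_numpy())
        res = cross_validate_10fold(
            perm, feature_sets, cohort.ontologies, acfg, seed=2,
        )
        assert 0.35 <= res.auc_roc <= 0.65
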
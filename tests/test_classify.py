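"""Compound covariate predictor, companions, cross-validation, evaluation."""

import math

import numpy as np
import pandas as pd
import pytest

from pbmcsig import (
    CCPModel,
    CompoundCovariatePredictor,
    CVConfig,
    ExpressionMatrix,
    ccp_classify,
    companion_classify,
    evaluate_predictions,
    kfold_cross_validate,
    select_predictor_genes,
    simulate_expression,
    train_ccp,
    two_sample_t,
)
from pbmcsig.exceptions import DegenerateDataError, DomainError

from conftest import clean_config

# the published eight-gene predictor: weights are training t statistics,
# decision rule sum(w_i * x_i) > 38.98
PUBLISHED_GENES = ["SSBP2", "Ube2b-rs1", "CA5B", "F5",
                   "TBC1D8", "ANXA3", "ARG1", "ADAMTS20"]
PUBLISHED_WEIGHTS = [-4.97, -4.83, -4.38, 4.43, 4.44, 4.53, 4.84, 4.96]
PUBLISHED_THRESHOLD = 38.98


def _em(rows: dict, samples=None) -> ExpressionMatrix:
    df = pd.DataFrame(rows).T
    df.index.name = "spot_id"
    if samples is not None:
        df.columns = samples
    return ExpressionMatrix(values=df)


class TestTwoSampleT:
    def test_hand_example(self):
        t = two_sample_t([0, 2, 4, 6], ["c", "c", "x", "x"], case_label="x")
        assert t == pytest.approx(2.8284, abs=1e-4)

    def test_equal_means_zero(self):
        assert two_sample_t([1, 3, 1, 3], ["c", "c", "x", "x"], "x") == pytest.approx(0.0)

    def test_antisymmetric_in_labels(self):
        vals = [0.3, 1.2, 2.4, 3.1]
        t1 = two_sample_t(vals, ["c", "c", "x", "x"], "x")
        t2 = two_sample_t(vals, ["x", "x", "c", "c"], "x")
        assert t1 == pytest.approx(-t2)

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateDataError):
            two_sample_t([1, 1, 1, 1], ["c", "c", "x", "x"], "x")


class TestGeneSelection:
    def _screen_data(self):
        # 3 genes engineered: strong+large fold, strong+small fold, weak+large fold
        rng = np.random.default_rng(37)
        n = 20
        labels = pd.Series(["case"] * n + ["control"] * n,
                           index=[f"a{i}" for i in range(2 * n)])
        strong_big = np.r_[rng.normal(1.0, 0.1, n), rng.normal(0.0, 0.1, n)]
        strong_small = np.r_[rng.normal(0.2, 0.05, n), rng.normal(0.0, 0.05, n)]
        weak_big = np.r_[rng.normal(1.0, 2.5, n), rng.normal(0.0, 2.5, n)]
        m = _em({"strong_big": strong_big, "strong_small": strong_small,
                 "weak_big": weak_big}, samples=labels.index)
        return m, labels

    def test_both_criteria_required(self):
        m, labels = self._screen_data()
        sel = select_predictor_genes(m, labels, p_max=1e-4, min_fold=1.5)
        assert list(sel) == ["strong_big"]

    def test_empty_selection_allowed(self):
        m, labels = self._screen_data()
        sel = select_predictor_genes(m, labels, p_max=1e-30, min_fold=50.0)
        assert len(sel) == 0


class TestCCP:
    def test_single_gene_hand_example(self):
        labels = pd.Series(["control", "control", "case", "case"],
                           index=["a1", "a2", "a3", "a4"])
        m = _em({"g": [0.0, 2.0, 4.0, 6.0]}, samples=labels.index)
        model = train_ccp(m, labels, ["g"])
        assert model.weights[0] == pytest.approx(2.8284, abs=1e-4)
        assert model.threshold == pytest.approx(8.485, abs=1e-3)

    def test_label_swap_leaves_predictions_invariant(self):
        rng = np.random.default_rng(41)
        labels = pd.Series(["case"] * 5 + ["control"] * 5,
                           index=[f"a{i}" for i in range(10)])
        m = _em({"g1": rng.normal(0, 1, 10) + np.r_[np.ones(5), np.zeros(5)],
                 "g2": rng.normal(0, 1, 10)}, samples=labels.index)
        model_case = train_ccp(m, labels, ["g1", "g2"], case_label="case")
        model_ctrl = train_ccp(m, labels, ["g1", "g2"], case_label="control")
        np.testing.assert_allclose(model_ctrl.weights, -model_case.weights)
        assert model_ctrl.threshold == pytest.approx(-model_case.threshold)
        for s in m.sample_ids:
            _, l1 = ccp_classify(model_case, m.values[s])
            _, l2 = ccp_classify(model_ctrl, m.values[s])
            # opposite positive labels, same partition of samples
            assert (l1 == "case") == (l2 != "control")

    def test_affine_shift_of_one_gene_cancels(self):
        rng = np.random.default_rng(43)
        labels = pd.Series(["case"] * 6 + ["control"] * 6,
                           index=[f"a{i}" for i in range(12)])
        g1 = rng.normal(0, 1, 12) + np.r_[np.ones(6), np.zeros(6)]
        g2 = rng.normal(0, 1, 12)
        m1 = _em({"g1": g1, "g2": g2}, samples=labels.index)
        m2 = _em({"g1": g1 + 7.0, "g2": g2}, samples=labels.index)
        mod1 = train_ccp(m1, labels, ["g1", "g2"])
        mod2 = train_ccp(m2, labels, ["g1", "g2"])
        for s in labels.index:
            s1, l1 = ccp_classify(mod1, m1.values[s])
            s2, l2 = ccp_classify(mod2, m2.values[s])
            assert l1 == l2
            assert s2 - s1 == pytest.approx(mod1.weights[0] * 7.0, rel=1e-9)

    def test_published_model_round_trips_and_classifies(self, tmp_path):
        model = CCPModel(genes=PUBLISHED_GENES,
                         weights=np.array(PUBLISHED_WEIGHTS),
                         threshold=PUBLISHED_THRESHOLD,
                         positive_label="PC", negative_label="non-PC")
        p = tmp_path / "model.tsv"
        model.save(p)
        back = CCPModel.load(p)
        assert back.genes == PUBLISHED_GENES
        np.testing.assert_array_equal(back.weights, PUBLISHED_WEIGHTS)
        assert back.threshold == PUBLISHED_THRESHOLD

        # uniform probe x_i = 10: score is 10 * sum(w) = 90.2 -> case
        score, label = ccp_classify(back, {g: 10.0 for g in PUBLISHED_GENES})
        assert score == pytest.approx(90.2, abs=1e-9)
        assert label == "PC"
        # all-zero probe scores 0 <= threshold -> control
        _, label0 = ccp_classify(back, {g: 0.0 for g in PUBLISHED_GENES})
        assert label0 == "non-PC"

    def test_score_equal_to_threshold_is_negative(self):
        model = CCPModel(genes=["g"], weights=np.array([1.0]), threshold=5.0,
                         positive_label="PC", negative_label="non-PC")
        _, label = ccp_classify(model, {"g": 5.0})
        assert label == "non-PC"   # rule is strictly greater
        _, label = ccp_classify(model, {"g": 5.0 + 1e-9})
        assert label == "PC"

    def test_missing_gene_is_error_without_imputation(self):
        model = CCPModel(genes=["g1", "g2"], weights=np.array([1.0, 1.0]),
                         threshold=0.0)
        with pytest.raises(DomainError, match="g2"):
            ccp_classify(model, {"g1": 1.0})


class TestCompanions:
    def _train(self):
        labels = pd.Series(["control", "control", "case", "case"],
                           index=["a1", "a2", "a3", "a4"])
        m = _em({"g": [0.0, 2.0, 4.0, 6.0]}, samples=labels.index)
        return m, labels

    @pytest.mark.parametrize("x,expected", [(1.0, "control"), (5.0, "case")])
    def test_dlda_midpoint_boundary(self, x, expected):
        m, labels = self._train()
        assert companion_classify("dlda", m, labels, {"g": x}) == expected

    def test_nearest_centroid(self):
        m, labels = self._train()
        # centroids 1 and 5; 2.9 is nearer 1
        assert companion_classify("nearest_centroid", m, labels, {"g": 2.9}) == "control"

    def test_knn1_exact_training_point(self):
        m, labels = self._train()
        assert companion_classify("knn1", m, labels, {"g": 6.0}) == "case"
        assert companion_classify("knn1", m, labels, {"g": 0.0}) == "control"

    def test_knn3_majority(self):
        m, labels = self._train()
        # neighbours of 3.5: {4 (case), 2 (control), 6 (case)} -> case
        assert companion_classify("knn3", m, labels, {"g": 3.5}) == "case"

    def test_ccp_single_gene_matches_dlda_boundary(self):
        # equal class sizes, one gene: both rules threshold at the midpoint
        m, labels = self._train()
        model = train_ccp(m, labels, ["g"])
        for x in [2.99, 3.01, 1.0, 5.0]:
            _, ccp_label = ccp_classify(model, {"g": x})
            dlda_label = companion_classify("dlda", m, labels, {"g": x})
            ccp_label = "case" if ccp_label == model.positive_label else "control"
            assert ccp_label == dlda_label

    def test_unknown_method_rejected(self):
        m, labels = self._train()
        with pytest.raises(DomainError):
            companion_classify("svm", m, labels, {"g": 1.0})


class TestEvaluation:
    def test_blinded_validation_arithmetic(self):
        # 12 cases with 10 called correctly, 12 controls with 9 correct
        perf = evaluate_predictions(
            ["PC"] * 10 + ["non-PC"] * 2 + ["non-PC"] * 9 + ["PC"] * 3,
            ["PC"] * 12 + ["non-PC"] * 12,
            positive_label="PC")
        assert perf.sensitivity == pytest.approx(10 / 12)
        assert perf.specificity == pytest.approx(0.75)
        assert perf.accuracy == pytest.approx(19 / 24)

    def test_degenerate_truths_warn(self):
        perf = evaluate_predictions(["PC", "PC"], ["non-PC", "non-PC"], "PC")
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            assert math.isnan(perf.sensitivity)
        assert perf.specificity == 0.0

    def test_all_positive_predictions(self):
        perf = evaluate_predictions(["PC"] * 4, ["PC", "PC", "non-PC", "non-PC"], "PC")
        assert perf.sensitivity == 1.0
        assert perf.specificity == 0.0


class TestCrossValidation:
    def test_perfect_separation_gives_accuracy_one(self):
        cfg = clean_config(
            n_case_subjects=20, n_control_subjects=20,
            n_genes=60, n_de_genes=10, de_log2fc_range=(3.0, 3.0),
            residual_sd=0.1, seed=47)
        m, s, _ = simulate_expression(cfg)
        _, perf = kfold_cross_validate(
            m, s.groups, CVConfig(k=10, p_max=1e-4, min_fold=1.5, seed=1))
        assert perf.accuracy == 1.0

    def test_loo_deterministic(self):
        cfg = clean_config(n_case_subjects=8, n_control_subjects=8,
                           n_genes=40, n_de_genes=5, de_log2fc_range=(2.0, 2.0),
                           residual_sd=0.3, seed=53)
        m, s, _ = simulate_expression(cfg)
        cv = CVConfig(k=m.n_samples, seed=5)
        preds1, perf1 = kfold_cross_validate(m, s.groups, cv)
        preds2, perf2 = kfold_cross_validate(m, s.groups, cv)
        pd.testing.assert_frame_equal(preds1, preds2)
        assert perf1 == perf2

    def test_noise_with_in_fold_selection_stays_near_chance(self):
        # pure noise: the unbiased protocol must not manufacture signal
        accs = []
        n_pred = 0
        for seed in (61, 62, 63):
            cfg = clean_config(n_case_subjects=20, n_control_subjects=20,
                               n_genes=500, n_de_genes=0,
                               residual_sd=0.5, seed=seed)
            m, s, _ = simulate_expression(cfg)
            _, perf = kfold_cross_validate(
                m, s.groups, CVConfig(k=5, p_max=1e-4, min_fold=1.5, seed=seed))
            accs.append(perf.accuracy * perf.total)
            n_pred += perf.total
        acc = sum(accs) / n_pred
        assert abs(acc - 0.5) <= 3 * math.sqrt(0.25 / n_pred)

    def test_selection_before_folds_inflates_noise_accuracy(self):
        # deliberately biased protocol: pick the best-separating genes on ALL
        # samples first, then cross-validate on only those genes
        cfg = clean_config(n_case_subjects=20, n_control_subjects=20,
                           n_genes=2000, n_de_genes=0, residual_sd=0.5, seed=67)
        m, s, _ = simulate_expression(cfg)
        labels = s.groups
        lab = labels.to_numpy(dtype=object)
        vals = m.values.to_numpy()
        tstats = []
        for i in range(m.n_spots):
            tstats.append(abs(two_sample_t(vals[i], lab, "case")))
        top = m.spot_ids[np.argsort(tstats)[::-1][:10]]
        biased_m = m.subset_spots(top)
        # p_max=1 keeps every pre-chosen gene inside each fold
        _, biased = kfold_cross_validate(
            biased_m, labels, CVConfig(k=5, p_max=1.0, min_fold=1.0, seed=67))
        _, unbiased = kfold_cross_validate(
            m, labels, CVConfig(k=5, p_max=1e-4, min_fold=1.5, seed=67))
        assert biased.accuracy > 0.62
        assert biased.accuracy - unbiased.accuracy > 0.1

    def test_model_results_surface(self, small_experiment):
        m, s, _ = small_experiment
        res = CompoundCovariatePredictor(m, s.groups, p_max=1e-3,
                                         min_fold=1.5, impute=True).fit()
        pred = res.predict(m)
        assert set(pred.columns) == {"score", "label"}
        perf = res.evaluate(m, s.groups)
        assert perf.total == m.n_samples
        assert "threshold" in res.summary()
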
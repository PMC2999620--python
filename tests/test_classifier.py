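import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import auc_brute
from conftest import make_annotation
from seropanel.classifier import (
    ClassConditionalModel,
    ClassifierMetrics,
    PanelClassifier,
    auc_from_scores,
    classifier_from_dict,
    classifier_to_dict,
    evaluate,
    log_likelihood_ratio,
    llr_array,
    metrics_from_calls,
    posterior_case,
    train_panel,
    wilson_interval,
)
from seropanel.errors import ScoringError, TrainingError
from seropanel.io import AnalyteMatrix
from seropanel.lognormal import fit_or_fallback


def one_marker_classifier(mu_case=1.0, mu_ctrl=0.0, sigma=1.0, prior=0.5):
    return PanelClassifier(
        panel=("A1",),
        case_models={"A1": ClassConditionalModel("A1", "case", mu_case, sigma)},
        control_models={"A1": ClassConditionalModel("A1", "control", mu_ctrl, sigma)},
        prior_case=prior,
    )


class TestTrainPanel:
    def test_delegates_to_fit_module(self, two_site_cohort):
        _, matrix, annotations = two_site_cohort
        clf = train_panel(matrix, annotations, ["A0000"])
        cases = np.array([a.is_case for a in annotations])
        expected, _ = fit_or_fallback(matrix.column("A0000")[cases])
        assert clf.case_models["A0000"].mu == expected.mu
        assert clf.case_models["A0000"].sigma == expected.sigma

    def test_symmetry_on_identical_classes(self):
        rng = np.random.default_rng(0)
        values = np.exp(rng.normal(1, 0.3, size=(40, 1)))
        values = np.vstack([values, values])  # controls repeat the case data
        matrix = AnalyteMatrix([f"S{i}" for i in range(80)], ["A1"], values)
        annotations = [
            make_annotation(f"S{i}", "case" if i < 40 else "control")
            for i in range(80)
        ]
        clf = train_panel(matrix, annotations, ["A1"])
        assert clf.case_models["A1"].mu == pytest.approx(clf.control_models["A1"].mu)
        assert clf.case_models["A1"].sigma == pytest.approx(clf.control_models["A1"].sigma)

    def test_single_class_rejected(self):
        matrix = AnalyteMatrix(["S1", "S2"], ["A1"], [[1.0], [2.0]])
        annotations = [make_annotation("S1", "case"), make_annotation("S2", "case")]
        with pytest.raises(TrainingError):
            train_panel(matrix, annotations, ["A1"])

    def test_12_marker_fits_converge(self, planted_training_cohort):
        _, matrix, annotations = planted_training_cohort
        clf = train_panel(matrix, annotations, matrix.analyte_ids[:12])
        for models in (clf.case_models, clf.control_models):
            assert all(m.converged for m in models.values())


class TestLogLikelihoodRatio:
    def test_identical_models_give_zero(self):
        clf = one_marker_classifier(0.0, 0.0)
        assert log_likelihood_ratio(clf, {"A1": 5.0}) == pytest.approx(0.0)

    def test_equidistant_point(self):
        clf = one_marker_classifier()
        assert log_likelihood_ratio(clf, {"A1": math.exp(0.5)}) == pytest.approx(0.0)

    def test_hand_computed_point(self):
        clf = one_marker_classifier()
        # x (log) = 1: -(0)^2/2 + (1)^2/2 = +0.5
        assert log_likelihood_ratio(clf, {"A1": math.exp(1.0)}) == pytest.approx(0.5)

    def test_missing_analyte_rejected(self):
        clf = one_marker_classifier()
        with pytest.raises(ScoringError):
            log_likelihood_ratio(clf, {"A2": 1.0})

    def test_additivity_over_disjoint_panels(self, two_site_cohort):
        _, matrix, annotations = two_site_cohort
        a = train_panel(matrix, annotations, ["A0000", "A0001"])
        b = train_panel(matrix, annotations, ["A0002"])
        both = train_panel(matrix, annotations, ["A0000", "A0001", "A0002"])
        sample = matrix.row(matrix.sample_ids[3])
        assert log_likelihood_ratio(both, sample) == pytest.approx(
            log_likelihood_ratio(a, sample) + log_likelihood_ratio(b, sample)
        )


class TestPosterior:
    def test_neutral(self):
        clf = one_marker_classifier(0.0, 0.0, prior=0.5)
        assert posterior_case(clf, {"A1": 7.0}) == pytest.approx(0.5)

    def test_half_llr(self):
        clf = one_marker_classifier()
        p = posterior_case(clf, {"A1": math.exp(1.0)})  # LLR = 0.5
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-0.5)))

    def test_prior_pass_through(self):
        clf = one_marker_classifier(0.0, 0.0, prior=0.2)
        assert posterior_case(clf, {"A1": 7.0}) == pytest.approx(0.2)

    @given(prior=st.floats(0.05, 0.95), x=st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_threshold_equivalence(self, prior, x):
        clf = one_marker_classifier(prior=prior)
        value = {"A1": math.exp(x)}
        llr = log_likelihood_ratio(clf, value)
        assert (posterior_case(clf, value) > 0.5) == (
            llr > math.log((1 - prior) / prior)
        )


class TestMetrics:
    def test_confusion_arithmetic(self):
        is_case = np.array([True] * 10 + [False] * 10)
        calls = np.array([True] * 9 + [False] + [True] * 2 + [False] * 8)
        m = metrics_from_calls(is_case, calls)
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.8)
        assert m.score == pytest.approx(1.7)

    def test_perfect_separation_auc(self):
        assert auc_from_scores([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_auc_example(self):
        assert auc_from_scores([0.9, 0.4], [0.6, 0.1]) == pytest.approx(0.75)

    @given(
        case=st.lists(st.floats(0, 1).map(lambda v: round(v, 2)), min_size=1, max_size=15),
        ctrl=st.lists(st.floats(0, 1).map(lambda v: round(v, 2)), min_size=1, max_size=15),
    )
    @settings(max_examples=80, deadline=None)
    def test_auc_matches_brute_force(self, case, ctrl):
        assert auc_from_scores(case, ctrl) == pytest.approx(
            auc_brute(case, ctrl), abs=1e-12
        )

    def test_wilson_interval_contains_estimate(self):
        lo, hi = wilson_interval(90, 100)
        assert lo < 0.9 < hi
        assert 0.0 <= lo and hi <= 1.0

    def test_absent_class_metrics_are_none(self):
        m = metrics_from_calls(np.array([False, False]), np.array([False, True]))
        assert m.sensitivity is None and m.score is None
        assert m.specificity == pytest.approx(0.5)


class TestEvaluate:
    def test_prior_monotonicity(self, two_site_cohort):
        _, matrix, annotations = two_site_cohort
        panel = ["A0000", "A0001"]
        results = []
        for prior in (0.1, 0.3, 0.5, 0.7, 0.9):
            clf = train_panel(matrix, annotations, panel, prior_case=prior)
            results.append(evaluate(clf, matrix, annotations))
        sens = [m.sensitivity for m in results]
        spec = [m.specificity for m in results]
        assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(spec, spec[1:]))

    def test_stage1_sensitivity_present(self, two_site_cohort):
        _, matrix, annotations = two_site_cohort
        clf = train_panel(matrix, annotations, ["A0000", "A0001"])
        m = evaluate(clf, matrix, annotations)
        assert m.stage1_sensitivity is not None
        assert 0.0 <= m.stage1_sensitivity <= 1.0

    def test_llr_array_matches_scalar_path(self, two_site_cohort):
        _, matrix, annotations = two_site_cohort
        clf = train_panel(matrix, annotations, ["A0000", "A0003"])
        vec = llr_array(clf, matrix)
        for i in (0, 17, 101):
            assert vec[i] == pytest.approx(
                log_likelihood_ratio(clf, matrix.row(matrix.sample_ids[i]))
            )


class TestSerialization:
    def test_round_trip(self, two_site_cohort):
        _, matrix, annotations = two_site_cohort
        clf = train_panel(matrix, annotations, ["A0000", "A0001"], prior_case=0.3)
        back = classifier_from_dict(classifier_to_dict(clf))
        assert back.panel == clf.panel
        assert back.prior_case == clf.prior_case
        for a in clf.panel:
            assert back.case_models[a].mu == clf.case_models[a].mu
            assert back.control_models[a].sigma == clf.control_models[a].sigma
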
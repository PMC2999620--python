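"""Diagonal-covariance (naive Bayes) classifier over log concentrations.

Each panel analyte contributes an independent log-normal marginal per class;
the panel log-likelihood ratio is the sum of per-marker normal log-density
differences on log values, and the posterior folds in an adjustable class
prior: ``posterior = logistic(LLR + log(prior / (1 - prior)))``, with the
case call made at posterior > 0.5.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import ScoringError, SeropanelError, TrainingError
from .io import AnalyteMatrix, SampleAnnotation, case_mask
from .lognormal import fit_or_fallback

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ClassConditionalModel:
    """Fitted log-normal marginal for one analyte in one class."""

    analyte_id: str
    class_label: str
    mu: float
    sigma: float
    converged: bool = True
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.sigma <= 0 or not np.isfinite(self.sigma) or not np.isfinite(self.mu):
            raise SeropanelError(
                f"invalid marginal for {self.analyte_id}/{self.class_label}: "
                f"mu={self.mu}, sigma={self.sigma}"
            )


@dataclass(frozen=True)
class PanelClassifier:
    """Ordered marker panel + per-class marginals + class prior."""

    panel: tuple[str, ...]
    case_models: Mapping[str, ClassConditionalModel]
    control_models: Mapping[str, ClassConditionalModel]
    prior_case: float = 0.5

    def __post_init__(self) -> None:
        if not self.panel:
            raise TrainingError("panel must contain at least one analyte")
        if len(set(self.panel)) != len(self.panel):
            raise TrainingError("panel contains duplicate analytes")
        for models, label in ((self.case_models, "case"), (self.control_models, "control")):
            if set(models) != set(self.panel):
                raise TrainingError(f"{label} models do not cover exactly the panel")
        if not (0.0 < self.prior_case < 1.0):
            raise TrainingError(f"prior_case must be in (0, 1), got {self.prior_case}")

    @property
    def prior_log_odds(self) -> float:
        return math.log(self.prior_case / (1.0 - self.prior_case))


@dataclass(frozen=True)
class ClassifierMetrics:
    """Confusion-derived metrics; absent classes yield ``None`` components."""

    sensitivity: float | None
    specificity: float | None
    auc: float | None = None
    stage1_sensitivity: float | None = None
    n_cases: int = 0
    n_controls: int = 0
    sensitivity_ci: tuple[float, float] | None = None
    specificity_ci: tuple[float, float] | None = None

    @property
    def score(self) -> float | None:
        if self.sensitivity is None or self.specificity is None:
            return None
        return self.sensitivity + self.specificity


def train_panel(
    matrix: AnalyteMatrix,
    annotations: Sequence[SampleAnnotation],
    panel: Sequence[str],
    prior_case: float = 0.5,
) -> PanelClassifier:
    """Fit per-analyte per-class log-normal marginals for a marker panel."""
    cases = case_mask(annotations)
    if not cases.any() or cases.all():
        raise TrainingError("training requires both cases and controls")
    case_models: dict[str, ClassConditionalModel] = {}
    control_models: dict[str, ClassConditionalModel] = {}
    for analyte in panel:
        col = matrix.column(analyte)
        for mask, label, store in (
            (cases, "case", case_models),
            (~cases, "control", control_models),
        ):
            params, diag = fit_or_fallback(col[mask])
            store[analyte] = ClassConditionalModel(
                analyte, label, params.mu, params.sigma, diag.converged, diag.rss
            )
    return PanelClassifier(tuple(panel), case_models, control_models, prior_case)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _marker_llr(x: np.ndarray, case: ClassConditionalModel, ctrl: ClassConditionalModel) -> np.ndarray:
    zc = (x - case.mu) / case.sigma
    zk = (x - ctrl.mu) / ctrl.sigma
    return (
        -0.5 * zc * zc
        - math.log(case.sigma)
        + 0.5 * zk * zk
        + math.log(ctrl.sigma)
    )


def log_likelihood_ratio(
    classifier: PanelClassifier, sample_values: Mapping[str, float]
) -> float:
    """Sum over panel markers of the case-vs-control normal log density gap."""
    total = 0.0
    for analyte in classifier.panel:
        if analyte not in sample_values:
            raise ScoringError(f"sample is missing panel analyte {analyte!r}")
        value = float(sample_values[analyte])
        if not (value > 0) or not np.isfinite(value):
            raise ScoringError(f"non-positive value {value!r} for analyte {analyte!r}")
        x = np.array([math.log(value)])
        total += float(
            _marker_llr(x, classifier.case_models[analyte], classifier.control_models[analyte])[0]
        )
    return total


def posterior_case(
    classifier: PanelClassifier, sample_values: Mapping[str, float]
) -> float:
    """logistic(LLR + prior log odds); call case iff posterior > 0.5."""
    t = log_likelihood_ratio(classifier, sample_values) + classifier.prior_log_odds
    return 1.0 / (1.0 + math.exp(-t))


def llr_array(classifier: PanelClassifier, matrix: AnalyteMatrix) -> np.ndarray:
    """Vectorized per-sample LLR for every sample of a matrix."""
    total = np.zeros(matrix.n_samples)
    for analyte in classifier.panel:
        x = np.log(matrix.column(analyte))
        total += _marker_llr(
            x, classifier.case_models[analyte], classifier.control_models[analyte]
        )
    return total


def posterior_array(classifier: PanelClassifier, matrix: AnalyteMatrix) -> np.ndarray:
    t = llr_array(classifier, matrix) + classifier.prior_log_odds
    return 1.0 / (1.0 + np.exp(-t))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Wilson score 95% interval for a binomial proportion."""
    if n == 0:
        raise SeropanelError("wilson_interval requires n >= 1")
    phat = k / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def auc_from_scores(case_scores, control_scores) -> float:
    """AUC as pairwise concordance with ties counting one half (midrank form)."""
    case_scores = np.asarray(case_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    if case_scores.size == 0 or control_scores.size == 0:
        raise SeropanelError("AUC requires scores from both classes")
    pooled = np.concatenate([case_scores, control_scores])
    ranks = rankdata(pooled)
    n1 = case_scores.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * control_scores.size))


def metrics_from_calls(
    is_case: np.ndarray,
    calls: np.ndarray,
    posteriors: np.ndarray | None = None,
    stage1_case: np.ndarray | None = None,
    with_ci: bool = False,
) -> ClassifierMetrics:
    """Assemble metrics from boolean truth/call vectors (and optional posteriors)."""
    is_case = np.asarray(is_case, dtype=bool)
    calls = np.asarray(calls, dtype=bool)
    n_cases = int(is_case.sum())
    n_controls = int((~is_case).sum())
    sens = spec = auc = stage1 = None
    sens_ci = spec_ci = None
    if n_cases:
        tp = int((calls & is_case).sum())
        sens = tp / n_cases
        if with_ci:
            sens_ci = wilson_interval(tp, n_cases)
    if n_controls:
        tn = int((~calls & ~is_case).sum())
        spec = tn / n_controls
        if with_ci:
            spec_ci = wilson_interval(tn, n_controls)
    if n_cases and n_controls and posteriors is not None:
        auc = auc_from_scores(posteriors[is_case], posteriors[~is_case])
    if stage1_case is not None:
        stage1_case = np.asarray(stage1_case, dtype=bool)
        k = int(stage1_case.sum())
        if k:
            stage1 = int((calls & stage1_case).sum()) / k
    return ClassifierMetrics(
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        stage1_sensitivity=stage1,
        n_cases=n_cases,
        n_controls=n_controls,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
    )


def evaluate(
    classifier: PanelClassifier,
    matrix: AnalyteMatrix,
    annotations: Sequence[SampleAnnotation],
    subset_mask: np.ndarray | None = None,
    with_ci: bool = False,
) -> ClassifierMetrics:
    """Sensitivity/specificity at posterior 0.5, midrank AUC, stage-I sensitivity.

    Metrics whose class is absent from the subset are reported as ``None``.
    """
    if subset_mask is None:
        subset_mask = np.ones(matrix.n_samples, dtype=bool)
    subset_mask = np.asarray(subset_mask, dtype=bool)
    if not subset_mask.any():
        raise SeropanelError("evaluation subset is empty")
    sub_matrix = matrix.subset_samples(subset_mask)
    sub_ann = [a for a, keep in zip(annotations, subset_mask) if keep]
    posteriors = posterior_array(classifier, sub_matrix)
    is_case = case_mask(sub_ann)
    calls = posteriors > 0.5
    stage1 = np.array([a.is_case and a.stage == "I" for a in sub_ann], dtype=bool)
    return metrics_from_calls(is_case, calls, posteriors, stage1, with_ci=with_ci)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def classifier_to_dict(classifier: PanelClassifier) -> dict:
    def dump(models: Mapping[str, ClassConditionalModel]) -> dict:
        return {
            a: {"mu": m.mu, "sigma": m.sigma, "converged": m.converged}
            for a, m in models.items()
        }

    return {
        "panel": list(classifier.panel),
        "case_models": dump(classifier.case_models),
        "control_models": dump(classifier.control_models),
        "prior_case": classifier.prior_case,
    }


def classifier_from_dict(payload: Mapping) -> PanelClassifier:
    def load(models: Mapping, label: str) -> dict[str, ClassConditionalModel]:
        return {
            a: ClassConditionalModel(
                a, label, float(m["mu"]), float(m["sigma"]), bool(m.get("converged", True))
            )
            for a, m in models.items()
        }

    return PanelClassifier(
        panel=tuple(payload["panel"]),
        case_models=load(payload["case_models"], "case"),
        control_models=load(payload["control_models"], "control"),
        prior_case=float(payload["prior_case"]),
    )


def content_hash(payload: Mapping) -> str:
    canonical = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


__all__ = [
    "ClassConditionalModel",
    "PanelClassifier",
    "ClassifierMetrics",
    "train_panel",
    "log_likelihood_ratio",
    "posterior_case",
    "llr_array",
    "posterior_array",
    "evaluate",
    "metrics_from_calls",
    "auc_from_scores",
    "wilson_interval",
    "classifier_to_dict",
    "classifier_from_dict",
    "content_hash",
]
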
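"""Final classifier construction and verification.

Covers class-stratified k-fold assignment, fold-refit cross-validation with
pooled (micro-averaged) metrics, the ordered pre-specified criteria cascade,
final panel choice, model freezing, blinded verification against a
barcode-keyed class map, and demographic subgroup evaluation.

Blinding is enforced structurally: :func:`verify_blinded` is the only
operation in the package that accepts a :class:`~seropanel.io.BlindingKey`,
and it scores only a previously frozen (serialized, content-hashed) model.
"""

from __future__ import annotations

import datetime
import json
import operator
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classifier import (
    ClassifierMetrics,
    PanelClassifier,
    classifier_from_dict,
    classifier_to_dict,
    content_hash,
    evaluate,
    metrics_from_calls,
    posterior_array,
    train_panel,
)
from .errors import GateError, SelectionError, SeropanelError, UnblindingError
from .io import AnalyteMatrix, BlindingKey, SampleAnnotation, case_mask

_COMPARATORS = {">=": operator.ge, ">": operator.gt, "<=": operator.le, "<": operator.lt}

DEFAULT_GATE_CRITERIA: tuple[tuple[str, str, float], ...] = (
    ("training_score", ">=", 1.7),
    ("training_stage1_sensitivity", ">=", 0.85),
    ("cv_score", ">=", 1.7),
    ("cv_stage1_sensitivity", ">=", 0.85),
    ("severe_copd_specificity", ">=", 0.65),
)


@dataclass(frozen=True)
class CriteriaGate:
    """Ordered (metric, comparator, threshold) cascade."""

    criteria: tuple[tuple[str, str, float], ...] = DEFAULT_GATE_CRITERIA

    def __post_init__(self) -> None:
        for name, cmp, _ in self.criteria:
            if cmp not in _COMPARATORS:
                raise SeropanelError(f"unknown comparator {cmp!r} for metric {name!r}")


@dataclass(frozen=True)
class GatedPanel:
    """A candidate panel with every metric the gate may reference."""

    panel: tuple[str, ...]
    metrics: Mapping[str, float | None]

    @property
    def size(self) -> int:
        return len(self.panel)


@dataclass(frozen=True)
class CrossValidationResult:
    fold_metrics: tuple[ClassifierMetrics, ...]
    sensitivity: float
    specificity: float
    stage1_sensitivity: float | None
    auc: float | None

    @property
    def score(self) -> float:
        return self.sensitivity + self.specificity


# ---------------------------------------------------------------------------
# folds and cross-validation
# ---------------------------------------------------------------------------


def stratified_folds(
    annotations: Sequence[SampleAnnotation],
    k: int = 10,
    seed: int = 0,
    by_site: bool = False,
) -> np.ndarray:
    """Class-stratified fold ids (0..k-1) per sample, seed-deterministic.

    Within each stratum the shuffled samples are dealt round-robin starting at
    a shuffled fold offset, so per-fold class counts deviate from exact
    proportionality by at most one.
    """
    if k < 2:
        raise SeropanelError("k must be >= 2")
    rng = np.random.default_rng(seed)
    labels = [
        (a.class_label, a.site) if by_site else (a.class_label,) for a in annotations
    ]
    folds = np.empty(len(annotations), dtype=int)
    strata = sorted(set(labels))
    for stratum in strata:
        idx = np.array([i for i, lab in enumerate(labels) if lab == stratum])
        if idx.size < k:
            raise SeropanelError(
                f"stratum {stratum} has {idx.size} samples, fewer than k={k}"
            )
        perm = rng.permutation(idx)
        offset = int(rng.integers(k))
        folds[perm] = (np.arange(perm.size) + offset) % k
    return folds


def cross_validate(
    matrix: AnalyteMatrix,
    annotations: Sequence[SampleAnnotation],
    panel: Sequence[str],
    k: int = 10,
    prior_case: float = 0.5,
    seed: int = 0,
) -> CrossValidationResult:
    """k-fold CV with per-fold refit of every class-conditional marginal.

    Pooled metrics come from pooled held-out confusion counts (micro-average);
    the pooled AUC uses the pooled held-out posteriors.
    """
    folds = stratified_folds(annotations, k=k, seed=seed)
    n = matrix.n_samples
    posteriors = np.empty(n)
    fold_metrics: list[ClassifierMetrics] = []
    for fold in range(k):
        held = folds == fold
        train_matrix = matrix.subset_samples(~held)
        train_ann = [a for a, h in zip(annotations, held) if not h]
        clf = train_panel(train_matrix, train_ann, panel, prior_case)
        held_matrix = matrix.subset_samples(held)
        held_ann = [a for a, h in zip(annotations, held) if h]
        post = posterior_array(clf, held_matrix)
        posteriors[held] = post
        stage1 = np.array([a.is_case and a.stage == "I" for a in held_ann], dtype=bool)
        fold_metrics.append(
            metrics_from_calls(case_mask(held_ann), post > 0.5, post, stage1)
        )
    is_case = case_mask(annotations)
    calls = posteriors > 0.5
    stage1 = np.array([a.is_case and a.stage == "I" for a in annotations], dtype=bool)
    pooled = metrics_from_calls(is_case, calls, posteriors, stage1)
    if pooled.sensitivity is None or pooled.specificity is None:
        raise SeropanelError("cross-validation requires both classes")
    return CrossValidationResult(
        fold_metrics=tuple(fold_metrics),
        sensitivity=pooled.sensitivity,
        specificity=pooled.specificity,
        stage1_sensitivity=pooled.stage1_sensitivity,
        auc=pooled.auc,
    )


# ---------------------------------------------------------------------------
# gate metrics
# ---------------------------------------------------------------------------


def severe_copd_specificity(
    classifier: PanelClassifier,
    matrix: AnalyteMatrix,
    annotations: Sequence[SampleAnnotation],
) -> float | None:
    """Specificity among controls with the most severe airflow-obstruction grade."""
    mask = np.array(
        [(not a.is_case) and a.gold_grade == "III/IV" for a in annotations], dtype=bool
    )
    if not mask.any():
        return None
    m = evaluate(classifier, matrix, annotations, subset_mask=mask)
    return m.specificity


def panel_gate_metrics(
    matrix: AnalyteMatrix,
    annotations: Sequence[SampleAnnotation],
    panel: Sequence[str],
    k: int = 10,
    prior_case: float = 0.5,
    cv_seed: int = 0,
) -> GatedPanel:
    """Compute every default-gate metric for one panel (training + CV + subgroup)."""
    clf = train_panel(matrix, annotations, panel, prior_case)
    training = evaluate(clf, matrix, annotations)
    cv = cross_validate(matrix, annotations, panel, k=k, prior_case=prior_case, seed=cv_seed)
    metrics: dict[str, float | None] = {
        "training_sensitivity": training.sensitivity,
        "training_specificity": training.specificity,
        "training_score": training.score,
        "training_stage1_sensitivity": training.stage1_sensitivity,
        "training_auc": training.auc,
        "cv_sensitivity": cv.sensitivity,
        "cv_specificity": cv.specificity,
        "cv_score": cv.score,
        "cv_stage1_sensitivity": cv.stage1_sensitivity,
        "cv_auc": cv.auc,
        "severe_copd_specificity": severe_copd_specificity(clf, matrix, annotations),
    }
    return GatedPanel(panel=tuple(sorted(panel)), metrics=metrics)


def apply_criteria(
    panels: Sequence[GatedPanel], gate: CriteriaGate
) -> tuple[list[GatedPanel], list[int]]:
    """Apply the cascade in order; returns (survivors, count surviving each stage)."""
    survivors = list(panels)
    counts: list[int] = []
    for name, cmp, threshold in gate.criteria:
        passed = []
        for p in survivors:
            if name not in p.metrics or p.metrics[name] is None:
                raise GateError(
                    f"panel {';'.join(p.panel)} is missing gate metric {name!r}"
                )
            if _COMPARATORS[cmp](p.metrics[name], threshold):
                passed.append(p)
        survivors = passed
        counts.append(len(survivors))
    return survivors, counts


def choose_final(survivors: Sequence[GatedPanel]) -> GatedPanel:
    """Survivor with maximal CV score; ties: smaller panel, then lexicographic."""
    if not survivors:
        raise SelectionError("no panels survived the criteria gate")
    def key(p: GatedPanel):
        score = p.metrics.get("cv_score")
        if score is None:
            raise GateError(f"panel {';'.join(p.panel)} lacks cv_score")
        return (-score, p.size, p.panel)
    return sorted(survivors, key=key)[0]


# ---------------------------------------------------------------------------
# model freezing and blinded verification
# ---------------------------------------------------------------------------


def freeze_model(classifier: PanelClassifier, path, extra: Mapping | None = None) -> str:
    """Serialize a classifier to JSON with a content hash; returns the hash."""
    payload = classifier_to_dict(classifier)
    if extra:
        payload["run_info"] = dict(extra)
    digest = content_hash(payload)
    document = {"model": payload, "sha256": digest}
    Path(path).write_text(json.dumps(document, indent=2, sort_keys=True) + "\n")
    return digest


def load_frozen_model(path) -> tuple[PanelClassifier, str]:
    document = json.loads(Path(path).read_text())
    payload = document["model"]
    digest = content_hash(payload)
    if digest != document["sha256"]:
        raise SeropanelError(f"model file {path} failed its content-hash check")
    return classifier_from_dict(payload), digest


def _key_hash(key: BlindingKey) -> str:
    return content_hash({"key": dict(sorted(key.mapping.items()))})


def verify_blinded(
    model_path,
    matrix: AnalyteMatrix,
    barcodes: Mapping[str, str],
    key: BlindingKey,
    with_ci: bool = True,
) -> tuple[ClassifierMetrics, dict]:
    """Score verification samples with a frozen model and unblind via the key.

    ``barcodes`` maps sample_id -> barcode for every sample in ``matrix``.
    Returns the metrics and an audit record (model hash, key hash, timestamp).
    """
    classifier, model_hash = load_frozen_model(model_path)
    posteriors = posterior_array(classifier, matrix)
    truths = np.empty(matrix.n_samples, dtype=bool)
    for i, sid in enumerate(matrix.sample_ids):
        if sid not in barcodes:
            raise UnblindingError(f"sample {sid!r} has no barcode")
        barcode = barcodes[sid]
        if barcode not in key.mapping:
            raise UnblindingError(f"barcode {barcode!r} absent from blinding key")
        truths[i] = key.class_of(barcode) == "case"
    metrics = metrics_from_calls(truths, posteriors > 0.5, posteriors, with_ci=with_ci)
    audit = {
        "model_hash": model_hash,
        "key_hash": _key_hash(key),
        "n_samples": matrix.n_samples,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return metrics, audit


# ---------------------------------------------------------------------------
# subgroup metrics
# ---------------------------------------------------------------------------

SUBGROUPINGS = ("age_median", "smoking_status", "pack_years_median", "gold_grade")


def subgroup_metrics(
    classifier: PanelClassifier,
    matrix: AnalyteMatrix,
    annotations: Sequence[SampleAnnotation],
    grouping: str,
) -> dict[str, ClassifierMetrics]:
    """Evaluate per subgroup; metrics for absent classes come back as ``None``.

    Median splits are computed on samples with a known value; unknowns are
    excluded from the split groupings.
    """
    if grouping not in SUBGROUPINGS:
        raise SeropanelError(f"unknown grouping {grouping!r}")
    if grouping in ("age_median", "pack_years_median"):
        attr = "age" if grouping == "age_median" else "pack_years"
        values = np.array(
            [getattr(a, attr) if getattr(a, attr) is not None else np.nan for a in annotations]
        )
        known = ~np.isnan(values)
        if not known.any():
            raise SeropanelError(f"no known values for {attr}")
        med = float(np.median(values[known]))
        groups = {
            f"{attr}<=median": known & (values <= med),
            f"{attr}>median": known & (values > med),
        }
    elif grouping == "smoking_status":
        levels = sorted({a.smoking_status for a in annotations})
        groups = {
            lvl: np.array([a.smoking_status == lvl for a in annotations], dtype=bool)
            for lvl in levels
        }
    else:  # gold_grade
        levels = sorted({a.gold_grade for a in annotations})
        groups = {
            lvl: np.array([a.gold_grade == lvl for a in annotations], dtype=bool)
            for lvl in levels
        }
    out: dict[str, ClassifierMetrics] = {}
    for name, mask in groups.items():
        if mask.any():
            out[name] = evaluate(classifier, matrix, annotations, subset_mask=mask)
    return out


__all__ = [
    "CriteriaGate",
    "GatedPanel",
    "CrossValidationResult",
    "DEFAULT_GATE_CRITERIA",
    "stratified_folds",
    "cross_validate",
    "panel_gate_metrics",
    "severe_copd_specificity",
    "apply_criteria",
    "choose_final",
    "freeze_model",
    "load_frozen_model",
    "verify_blinded",
    "subgroup_metrics",
    "SUBGROUPINGS",
]
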
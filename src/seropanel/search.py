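"""Greedy forward beam search over marker panels.

Panels are scored by sensitivity + specificity.  All single-marker panels are
scored first; at each size the retained panels are extended by every unused
candidate, duplicates (same marker set reached by different orders) are
merged, and the best ``beam_width`` panels are kept, ties broken
lexicographically by sorted analyte ids.  The search stops when the best score
plateaus for two consecutive sizes, deteriorates, or the size cap is reached.

Because the naive Bayes LLR is additive over markers, every candidate's
per-sample LLR column is fitted once up front and panel scores are computed by
summing columns, which makes the expansion step a vectorized array sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .classifier import ClassifierMetrics
from .errors import SeropanelError, TrainingError
from .io import AnalyteMatrix, SampleAnnotation, case_mask
from .lognormal import fit_or_fallback


@dataclass(frozen=True)
class BeamSearchConfig:
    beam_width: int = 10_000
    max_panel_size: int = 15
    min_panel_size_for_output: int = 1
    scoring: str = "training"  # or "cross_validated"
    plateau_tolerance: float = 1e-6
    plateau_patience: int = 2
    prior_case: float = 0.5
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if self.beam_width < 1 or self.max_panel_size < 1:
            raise SeropanelError("beam_width and max_panel_size must be >= 1")
        if self.scoring not in ("training", "cross_validated"):
            raise SeropanelError(f"unknown scoring mode {self.scoring!r}")


@dataclass(frozen=True)
class ScoredPanel:
    """A retained panel with its sensitivity + specificity score."""

    panel: tuple[str, ...]  # sorted analyte ids
    score: float
    metrics: ClassifierMetrics

    @property
    def size(self) -> int:
        return len(self.panel)


def _fit_llr_columns(
    matrix: AnalyteMatrix,
    candidates: Sequence[str],
    cases: np.ndarray,
) -> np.ndarray:
    """Per-sample, per-candidate LLR contribution (n_samples x n_candidates)."""
    cols = np.empty((matrix.n_samples, len(candidates)))
    for j, analyte in enumerate(candidates):
        raw = matrix.column(analyte)
        x = np.log(raw)
        case_p, _ = fit_or_fallback(raw[cases])
        ctrl_p, _ = fit_or_fallback(raw[~cases])
        zc = (x - case_p.mu) / case_p.sigma
        zk = (x - ctrl_p.mu) / ctrl_p.sigma
        cols[:, j] = (
            -0.5 * zc * zc - math.log(case_p.sigma) + 0.5 * zk * zk + math.log(ctrl_p.sigma)
        )
    return cols


def beam_search(
    matrix: AnalyteMatrix,
    annotations: Sequence[SampleAnnotation],
    candidate_analytes: Sequence[str],
    config: BeamSearchConfig | None = None,
    seed: int = 0,
) -> list[ScoredPanel]:
    """Run the beam search; returns retained panels of every explored size.

    ``seed`` is accepted for interface uniformity and run metadata; the search
    itself is deterministic.
    """
    del seed  # deterministic; kept for interface/run-metadata uniformity
    config = config or BeamSearchConfig()
    candidates = list(dict.fromkeys(candidate_analytes))
    if not candidates:
        raise SeropanelError("beam_search requires at least one candidate analyte")
    cases = case_mask(annotations)
    if not cases.any() or cases.all():
        raise TrainingError("beam_search requires both classes present")

    if config.scoring == "cross_validated":
        score_panels = _make_cv_scorer(matrix, annotations, config)
        return _generic_beam(candidates, config, score_panels)

    cols = _fit_llr_columns(matrix, candidates, cases)
    threshold = math.log((1.0 - config.prior_case) / config.prior_case)
    case_idx = np.flatnonzero(cases)
    ctrl_idx = np.flatnonzero(~cases)
    n_case, n_ctrl = case_idx.size, ctrl_idx.size

    def sens_spec(llr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pos = llr > threshold
        sens = pos[..., case_idx].sum(axis=-1) / n_case
        spec = (~pos[..., ctrl_idx]).sum(axis=-1) / n_ctrl
        return sens, spec

    results: list[ScoredPanel] = []
    c = len(candidates)

    # size-1 panels
    sens1, spec1 = sens_spec(cols.T)
    scores1 = sens1 + spec1
    singles = sorted(
        range(c), key=lambda j: (-scores1[j], (candidates[j],))
    )[: config.beam_width]
    beam_members = [(j,) for j in singles]
    beam_llr = cols[:, [m[0] for m in beam_members]].T.copy()
    beam_scores = scores1[[m[0] for m in beam_members]]
    _emit(results, beam_members, sens1, spec1, candidates, 1, config)

    best_overall = float(np.max(beam_scores))
    stale = 0

    size = 1
    while size < config.max_panel_size and len(candidates) > size:
        member_mask = np.zeros((len(beam_members), c), dtype=bool)
        for b, members in enumerate(beam_members):
            member_mask[b, list(members)] = True

        all_scores = np.full((c, len(beam_members)), -np.inf)
        all_sens = np.zeros_like(all_scores)
        all_spec = np.zeros_like(all_scores)
        for cand in range(c):
            new_llr = beam_llr + cols[:, cand]
            sens, spec = sens_spec(new_llr)
            sc = sens + spec
            sc[member_mask[:, cand]] = -np.inf
            all_scores[cand] = sc
            all_sens[cand] = sens
            all_spec[cand] = spec

        flat = all_scores.ravel()
        order = np.argsort(-flat, kind="stable")
        picked: dict[tuple[int, ...], tuple[float, int, int]] = {}
        cutoff_score = -np.inf
        for pos_ in order:
            s = flat[pos_]
            if not np.isfinite(s):
                break
            if len(picked) >= config.beam_width and s < cutoff_score:
                break
            cand, b = divmod(int(pos_), len(beam_members))
            key = tuple(sorted(beam_members[b] + (cand,)))
            if key in picked:
                continue
            picked[key] = (float(s), cand, b)
            if len(picked) == config.beam_width:
                cutoff_score = float(s)
        chosen = sorted(
            picked.items(),
            key=lambda kv: (-kv[1][0], tuple(sorted(candidates[j] for j in kv[0]))),
        )[: config.beam_width]

        size += 1
        beam_members = [key for key, _ in chosen]
        new_llr = np.empty((len(chosen), matrix.n_samples))
        for b, (key, (_, cand, src)) in enumerate(chosen):
            new_llr[b] = beam_llr[src] + cols[:, cand]
        beam_llr = new_llr
        beam_scores = np.array([v[0] for _, v in chosen])
        sens_b = np.array([all_sens[v[1], v[2]] for _, v in chosen])
        spec_b = np.array([all_spec[v[1], v[2]] for _, v in chosen])
        _emit_sized(results, beam_members, sens_b, spec_b, candidates, config)

        best_size = float(beam_scores[0])
        improvement = best_size - best_overall
        if improvement < 0:
            break
        if improvement <= config.plateau_tolerance:
            stale += 1
            if stale >= config.plateau_patience:
                break
        else:
            stale = 0
            best_overall = best_size
    return results


def _emit(
    results: list[ScoredPanel],
    members: list[tuple[int, ...]],
    sens: np.ndarray,
    spec: np.ndarray,
    candidates: list[str],
    size: int,
    config: BeamSearchConfig,
) -> None:
    if size < config.min_panel_size_for_output:
        return
    for m in members:
        j = m[0]
        results.append(
            ScoredPanel(
                panel=tuple(sorted(candidates[i] for i in m)),
                score=float(sens[j] + spec[j]),
                metrics=ClassifierMetrics(
                    sensitivity=float(sens[j]), specificity=float(spec[j])
                ),
            )
        )


def _emit_sized(
    results: list[ScoredPanel],
    members: list[tuple[int, ...]],
    sens: np.ndarray,
    spec: np.ndarray,
    candidates: list[str],
    config: BeamSearchConfig,
) -> None:
    if members and len(members[0]) < config.min_panel_size_for_output:
        return
    for b, m in enumerate(members):
        results.append(
            ScoredPanel(
                panel=tuple(sorted(candidates[i] for i in m)),
                score=float(sens[b] + spec[b]),
                metrics=ClassifierMetrics(
                    sensitivity=float(sens[b]), specificity=float(spec[b])
                ),
            )
        )


def _make_cv_scorer(
    matrix: AnalyteMatrix,
    annotations: Sequence[SampleAnnotation],
    config: BeamSearchConfig,
) -> Callable[[list[tuple[str, ...]]], list[tuple[float, float]]]:
    from .pipeline import cross_validate  # local import: avoids a hard cycle

    def score(panels: list[tuple[str, ...]]) -> list[tuple[float, float]]:
        out = []
        for panel in panels:
            cv = cross_validate(
                matrix, annotations, panel, k=config.cv_folds,
                prior_case=config.prior_case, seed=0,
            )
            out.append((cv.sensitivity, cv.specificity))
        return out

    return score


def _generic_beam(
    candidates: list[str],
    config: BeamSearchConfig,
    score_panels: Callable[[list[tuple[str, ...]]], list[tuple[float, float]]],
) -> list[ScoredPanel]:
    """Slow path used for cross-validated scoring (small instances only)."""
    results: list[ScoredPanel] = []
    beam: list[tuple[str, ...]] = [(a,) for a in candidates]
    best_overall = -np.inf
    stale = 0
    size = 1
    while True:
        scored = score_panels(beam)
        ranked = sorted(
            zip(beam, scored),
            key=lambda t: (-(t[1][0] + t[1][1]), tuple(sorted(t[0]))),
        )[: config.beam_width]
        if size >= config.min_panel_size_for_output:
            for panel, (sens, spec) in ranked:
                results.append(
                    ScoredPanel(
                        panel=tuple(sorted(panel)),
                        score=sens + spec,
                        metrics=ClassifierMetrics(sensitivity=sens, specificity=spec),
                    )
                )
        best_size = ranked[0][1][0] + ranked[0][1][1]
        improvement = best_size - best_overall
        if size > 1:
            if improvement < 0:
                break
            if improvement <= config.plateau_tolerance:
                stale += 1
                if stale >= config.plateau_patience:
                    break
            else:
                stale = 0
        best_overall = max(best_overall, best_size)
        if size >= config.max_panel_size or size >= len(candidates):
            break
        seen: set[tuple[str, ...]] = set()
        next_beam: list[tuple[str, ...]] = []
        for panel, _ in ranked:
            for cand in candidates:
                if cand in panel:
                    continue
                key = tuple(sorted(panel + (cand,)))
                if key not in seen:
                    seen.add(key)
                    next_beam.append(key)
        beam = next_beam
        size += 1
    return results


def marker_frequency(
    panels: Sequence[ScoredPanel],
    score_threshold: float,
    min_size: int = 1,
) -> dict[str, int]:
    """Count, per analyte, retained panels with score >= threshold containing it."""
    counts: dict[str, int] = {}
    for sp in panels:
        if sp.score >= score_threshold and sp.size >= min_size:
            for analyte in sp.panel:
                counts[analyte] = counts.get(analyte, 0) + 1
    return counts


def write_panels(panels: Sequence[ScoredPanel], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("size\tpanel\tsensitivity\tspecificity\tscore\n")
        for sp in panels:
            fh.write(
                f"{sp.size}\t{';'.join(sp.panel)}\t{sp.metrics.sensitivity!r}\t"
                f"{sp.metrics.specificity!r}\t{sp.score!r}\n"
            )


__all__ = [
    "BeamSearchConfig",
    "ScoredPanel",
    "beam_search",
    "marker_frequency",
    "write_panels",
]
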
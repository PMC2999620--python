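"""Six-analysis candidate selection producing the union biomarker set.

Two populations (all cases + benign-nodule controls; all cases + all other
controls) are each screened under three KS criteria (per-site, combined, and
both), a beam search is run on every resulting candidate set, and analytes
appearing in at least ``frequency_threshold`` retained panels with score >=
``score_threshold`` qualify.  The final set is the union of the six qualified
sets, with per-analyte provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SelectionError, SeropanelError
from .io import AnalyteMatrix, SampleAnnotation, case_mask
from .ks import ks_two_sample
from .search import BeamSearchConfig, ScoredPanel, beam_search, marker_frequency

logger = logging.getLogger(__name__)

CRITERIA = ("per_site", "combined", "both")


@dataclass(frozen=True)
class SelectionConfig:
    ks_threshold: float = 0.3
    frequency_threshold: float = 10
    score_threshold: float = 1.7
    exclusion_list: tuple[str, ...] = ()
    min_panel_size_for_frequency: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.ks_threshold <= 1.0):
            raise SeropanelError("ks_threshold must be in [0, 1]")
        if not (0.0 <= self.score_threshold <= 2.0):
            raise SeropanelError("score_threshold must be in [0, 2]")


@dataclass(frozen=True)
class AnalysisResult:
    name: str  # e.g. "pop1_per_site"
    population: int
    criterion: str
    candidates: tuple[str, ...]
    frequencies: dict[str, int]
    qualified: tuple[str, ...]
    panels: tuple[ScoredPanel, ...] = ()


@dataclass(frozen=True)
class SelectionReport:
    analyses: tuple[AnalysisResult, ...]
    union: tuple[str, ...]
    provenance: dict[str, tuple[str, ...]]
    config: SelectionConfig
    seed: int

    def to_dict(self) -> dict:
        return {
            "config": {
                "ks_threshold": self.config.ks_threshold,
                "frequency_threshold": self.config.frequency_threshold,
                "score_threshold": self.config.score_threshold,
                "exclusion_list": list(self.config.exclusion_list),
            },
            "seed": self.seed,
            "analyses": [
                {
                    "name": a.name,
                    "population": a.population,
                    "criterion": a.criterion,
                    "candidates": list(a.candidates),
                    "frequencies": dict(sorted(a.frequencies.items())),
                    "qualified": list(a.qualified),
                }
                for a in self.analyses
            ],
            "union": list(self.union),
            "provenance": {a: list(v) for a, v in sorted(self.provenance.items())},
        }


def define_populations(
    annotations: Sequence[SampleAnnotation],
) -> tuple[np.ndarray, np.ndarray]:
    """Population 1: cases + benign-nodule controls; population 2: cases + all
    other controls.  The masks overlap only on cases."""
    cases = case_mask(annotations)
    nodule = np.array(
        [a.control_subtype == "benign_nodule" for a in annotations], dtype=bool
    )
    other_ctrl = ~cases & ~nodule
    pop1 = cases | nodule
    pop2 = cases | other_ctrl
    if not nodule.any():
        raise SelectionError("population 1 has no benign-nodule controls")
    if not other_ctrl.any():
        raise SelectionError("population 2 has no non-nodule controls")
    return pop1, pop2


def _group_ks(
    values: np.ndarray, cases: np.ndarray, columns: Sequence[int]
) -> np.ndarray:
    out = np.empty(len(columns))
    a = values[cases]
    b = values[~cases]
    for i, j in enumerate(columns):
        out[i] = ks_two_sample(a[:, j], b[:, j])
    return out


def candidate_set(
    matrix: AnalyteMatrix,
    annotations: Sequence[SampleAnnotation],
    population_mask: np.ndarray,
    criterion: str,
    config: SelectionConfig | None = None,
) -> list[str]:
    """Analytes meeting the KS criterion within a population.

    ``per_site``: KS >= threshold in every evaluable site (sites lacking a
    class are skipped with a warning); ``combined``: KS >= threshold pooling
    all sites; ``both``: intersection.
    """
    config = config or SelectionConfig()
    if criterion not in CRITERIA:
        raise SeropanelError(f"unknown criterion {criterion!r}")
    population_mask = np.asarray(population_mask, dtype=bool)
    if not population_mask.any():
        raise SeropanelError("empty population")
    sub = matrix.subset_samples(population_mask)
    sub_ann = [a for a, keep in zip(annotations, population_mask) if keep]
    cases = case_mask(sub_ann)
    if not cases.any() or cases.all():
        raise SeropanelError("population must contain both classes")
    excluded = set(config.exclusion_list)
    columns = [
        j for j, aid in enumerate(sub.analyte_ids) if aid not in excluded
    ]
    ids = [sub.analyte_ids[j] for j in columns]

    selected: dict[str, np.ndarray] = {}
    if criterion in ("combined", "both"):
        ks = _group_ks(sub.values, cases, columns)
        selected["combined"] = ks >= config.ks_threshold
    if criterion in ("per_site", "both"):
        sites = np.array([a.site for a in sub_ann], dtype=object)
        keep = np.ones(len(columns), dtype=bool)
        evaluated_any = False
        for site in sorted(set(sites.tolist())):
            at_site = sites == site
            site_cases = cases & at_site
            site_ctrls = ~cases & at_site
            if not site_cases.any() or not site_ctrls.any():
                logger.warning(
                    "per-site criterion: site %s lacks a class, skipped", site
                )
                continue
            evaluated_any = True
            site_values = sub.values[at_site]
            site_case = cases[at_site]
            ks = _group_ks(site_values, site_case, columns)
            keep &= ks >= config.ks_threshold
        if not evaluated_any:
            raise SeropanelError("per-site criterion: no site has both classes")
        selected["per_site"] = keep

    if criterion == "both":
        mask = selected["combined"] & selected["per_site"]
    else:
        mask = selected[criterion]
    return [aid for aid, ok in zip(ids, mask) if ok]


def select_biomarkers(
    matrix: AnalyteMatrix,
    annotations: Sequence[SampleAnnotation],
    config: SelectionConfig | None = None,
    beam_config: BeamSearchConfig | None = None,
    seed: int = 0,
) -> SelectionReport:
    """Run the 2 populations x 3 criteria analyses and form the union set."""
    config = config or SelectionConfig()
    beam_config = beam_config or BeamSearchConfig()
    pop1, pop2 = define_populations(annotations)

    analyses: list[AnalysisResult] = []
    for pop_idx, pop_mask in ((1, pop1), (2, pop2)):
        sub_matrix = matrix.subset_samples(pop_mask)
        sub_ann = [a for a, keep in zip(annotations, pop_mask) if keep]
        for criterion in CRITERIA:
            name = f"pop{pop_idx}_{criterion}"
            candidates = candidate_set(matrix, annotations, pop_mask, criterion, config)
            if not candidates:
                logger.warning("analysis %s: empty candidate set", name)
                analyses.append(
                    AnalysisResult(name, pop_idx, criterion, (), {}, ())
                )
                continue
            panels = beam_search(sub_matrix, sub_ann, candidates, beam_config, seed)
            freqs = marker_frequency(
                panels,
                config.score_threshold,
                min_size=config.min_panel_size_for_frequency,
            )
            qualified = tuple(
                sorted(a for a, n in freqs.items() if n >= config.frequency_threshold)
            )
            analyses.append(
                AnalysisResult(
                    name, pop_idx, criterion, tuple(candidates), freqs, qualified,
                    tuple(panels),
                )
            )

    if all(len(a.candidates) == 0 for a in analyses):
        raise SelectionError(
            "all six candidate sets are empty; lower ks_threshold or check inputs"
        )

    provenance: dict[str, list[str]] = {}
    for a in analyses:
        for analyte in a.qualified:
            provenance.setdefault(analyte, []).append(a.name)
    union = tuple(sorted(provenance))
    return SelectionReport(
        analyses=tuple(analyses),
        union=union,
        provenance={a: tuple(v) for a, v in provenance.items()},
        config=config,
        seed=seed,
    )


__all__ = [
    "SelectionConfig",
    "AnalysisResult",
    "SelectionReport",
    "define_populations",
    "candidate_set",
    "select_biomarkers",
    "CRITERIA",
]
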
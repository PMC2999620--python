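"""Between-site, within-class variability audit per analyte.

For every analyte the disease KS (cases vs controls, all sites pooled) is
contrasted with the mean KS over the between-site comparisons computed within
each class separately (with 4 sites: 6 unordered pairs x 2 classes = 12
comparisons).  Analytes whose mean between-site KS reaches the flag threshold
(default 0.4) are marked as handling-sensitive; ordering by
``mean_site_ks - disease_ks`` puts artifact-like analytes first and
disease-like analytes last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .errors import SeropanelError
from .io import AnalyteMatrix, SampleAnnotation, case_mask
from .ks import ks_two_sample

logger = logging.getLogger(__name__)

_MIN_CELL = 2  # a KS on fewer than 2 points per side is uninformative


@dataclass(frozen=True)
class SiteVariabilityRecord:
    analyte_id: str
    disease_ks: float
    mean_site_ks: float
    flagged: bool

    @property
    def delta(self) -> float:
        return self.mean_site_ks - self.disease_ks


def site_variability(
    matrix: AnalyteMatrix,
    annotations: Sequence[SampleAnnotation],
    flag_threshold: float = 0.4,
) -> list[SiteVariabilityRecord]:
    """Audit every analyte for between-site, within-class variation."""
    cases = case_mask(annotations)
    sites = np.array([a.site for a in annotations], dtype=object)
    site_names = sorted(set(sites.tolist()))
    if len(site_names) < 2:
        raise SeropanelError("site variability audit requires at least 2 sites")

    cells: dict[tuple[str, bool], np.ndarray] = {}
    for site in site_names:
        for is_case in (True, False):
            mask = (sites == site) & (cases == is_case)
            if mask.sum() < _MIN_CELL:
                logger.warning(
                    "site %s %s cell has %d samples; its comparisons are skipped",
                    site, "case" if is_case else "control", int(mask.sum()),
                )
                continue
            cells[(site, is_case)] = mask

    comparisons = [
        (a, b, is_case)
        for a, b in combinations(site_names, 2)
        for is_case in (True, False)
        if (a, is_case) in cells and (b, is_case) in cells
    ]
    if not comparisons:
        raise SeropanelError("no evaluable between-site comparisons")

    records: list[SiteVariabilityRecord] = []
    values = matrix.values
    case_vals = values[cases]
    ctrl_vals = values[~cases]
    for j, analyte in enumerate(matrix.analyte_ids):
        disease_ks = ks_two_sample(case_vals[:, j], ctrl_vals[:, j])
        ks_list = [
            ks_two_sample(values[cells[(a, c)], j], values[cells[(b, c)], j])
            for a, b, c in comparisons
        ]
        mean_site_ks = float(np.mean(ks_list))
        records.append(
            SiteVariabilityRecord(
                analyte_id=analyte,
                disease_ks=float(disease_ks),
                mean_site_ks=mean_site_ks,
                flagged=mean_site_ks >= flag_threshold,
            )
        )
    return records


def order_for_display(report: Sequence[SiteVariabilityRecord]) -> list[str]:
    """Analyte ids sorted by ``mean_site_ks - disease_ks`` descending.

    Artifact-like analytes come first, disease-like last; ties resolve by
    analyte id.
    """
    ordered = sorted(report, key=lambda r: (-r.delta, r.analyte_id))
    return [r.analyte_id for r in ordered]


def export_heatmap_table(report: Sequence[SiteVariabilityRecord], path) -> None:
    """TSV of the audit in display order (the plotting layer is optional)."""
    by_id = {r.analyte_id: r for r in report}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("analyte_id\tdisease_ks\tmean_site_ks\tdelta\tflagged\n")
        for analyte in order_for_display(report):
            r = by_id[analyte]
            fh.write(
                f"{r.analyte_id}\t{r.disease_ks!r}\t{r.mean_site_ks!r}\t"
                f"{r.delta!r}\t{r.flagged}\n"
            )


__all__ = [
    "SiteVariabilityRecord",
    "site_variability",
    "order_for_display",
    "export_heatmap_table",
]
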
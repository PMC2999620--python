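"""Two-sample Kolmogorov-Smirnov distance, asymptotic p-values, and BH q-values.

The KS distance is evaluated just after each pooled value (right-continuous
empirical CDF convention), which handles ties and makes the statistic
invariant to any common strictly monotone transform of both samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SeropanelError
from .io import AnalyteMatrix, SampleAnnotation

_P_FLOOR = 5e-324  # smallest subnormal; keeps p in (0, 1]


def ks_two_sample(x, y) -> float:
    """sup_t |Fx(t) - Fy(t)| over the two empirical CDFs; in [0, 1]."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise SeropanelError("ks_two_sample requires two non-empty samples")
    xs = np.sort(x)
    ys = np.sort(y)
    grid = np.union1d(xs, ys)
    fx = np.searchsorted(xs, grid, side="right") / xs.size
    fy = np.searchsorted(ys, grid, side="right") / ys.size
    return float(np.max(np.abs(fx - fy)))


def ks_p_value(d: float, n: int, m: int) -> float:
    """Asymptotic two-sample Kolmogorov p-value.

    With effective size ne = n*m/(n+m):
    ``p = 2 * sum_{k>=1} (-1)^(k-1) * exp(-2 k^2 ne d^2)``, clipped to (0, 1].
    """
    if not (0.0 <= d <= 1.0):
        raise SeropanelError(f"KS distance must be in [0, 1], got {d}")
    if n < 1 or m < 1:
        raise SeropanelError("sample sizes must be >= 1")
    if d == 0.0:
        return 1.0
    ne = n * m / (n + m)
    a = 2.0 * ne * d * d
    total = 0.0
    for k in range(1, 201):
        term = math.exp(-a * k * k)
        total += term if k % 2 == 1 else -term
        if term < 1e-18:
            break
    p = 2.0 * total
    return float(min(1.0, max(_P_FLOOR, p)))


def bh_qvalues(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j``, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise SeropanelError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class MarkerScreenRecord:
    analyte_id: str
    ks: float
    p_value: float
    q_value: float
    direction: str  # 'up' / 'down': sign of median log(case) - median log(control)


def screen_markers(
    matrix: AnalyteMatrix,
    annotations: Sequence[SampleAnnotation],
    case_mask: np.ndarray,
    control_mask: np.ndarray,
) -> list[MarkerScreenRecord]:
    """KS screen of every analyte between two disjoint sample groups.

    BH q-values are computed over all screened analytes together; direction is
    the sign of the median log difference (case minus control), ties up.
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    control_mask = np.asarray(control_mask, dtype=bool)
    if case_mask.shape != (matrix.n_samples,) or control_mask.shape != (matrix.n_samples,):
        raise SeropanelError("masks must match the matrix sample count")
    if np.any(case_mask & control_mask):
        raise SeropanelError("case and control masks must be disjoint")
    if not case_mask.any() or not control_mask.any():
        raise SeropanelError("both groups must be non-empty")

    cases = matrix.values[case_mask]
    controls = matrix.values[control_mask]
    n, m = cases.shape[0], controls.shape[0]
    ks = np.empty(matrix.n_analytes)
    directions: list[str] = []
    log_case_med = np.median(np.log(cases), axis=0)
    log_ctrl_med = np.median(np.log(controls), axis=0)
    for j in range(matrix.n_analytes):
        ks[j] = ks_two_sample(cases[:, j], controls[:, j])
        directions.append("up" if log_case_med[j] >= log_ctrl_med[j] else "down")
    pvals = np.array([ks_p_value(d, n, m) for d in ks])
    qvals = bh_qvalues(pvals)
    return [
        MarkerScreenRecord(aid, float(ks[j]), float(pvals[j]), float(qvals[j]), directions[j])
        for j, aid in enumerate(matrix.analyte_ids)
    ]


def write_screen(records: Sequence[MarkerScreenRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("analyte_id\tks\tp_value\tq_value\tdirection\n")
        for r in records:
            fh.write(
                f"{r.analyte_id}\t{r.ks!r}\t{r.p_value!r}\t{r.q_value!r}\t{r.direction}\n"
            )


__all__ = [
    "ks_two_sample",
    "ks_p_value",
    "bh_qvalues",
    "MarkerScreenRecord",
    "screen_markers",
    "write_screen",
]
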
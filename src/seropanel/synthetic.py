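"""Synthetic multi-site case/control analyte matrices.

Each analyte j has a control log-mean mu_j and log-SD sigma_j.  Controls at
site s draw ``LogNormal(mu_j + o_{j,s} * sigma_j, sigma_j)`` and cases draw
``LogNormal(mu_j + o_{j,s} * sigma_j + delta_j * sigma_j, sigma_j)``, where
delta_j is zero except for planted disease markers and o_{j,s} is zero except
for planted site-handling-artifact analytes.  Disease effects are pure
location shifts in log space; site artifacts are class-independent.

For an equal-variance normal location shift of delta (in SD units) the
population two-sample KS distance is ``2 * Phi(delta / 2) - 1``, which the
planted effects are calibrated against in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from . import cohort
from .errors import ConfigError
from .io import AnalyteMatrix, SampleAnnotation

_HISTOLOGY_LEVELS = ("adenocarcinoma", "squamous", "large_cell", "nsclc_nos")
_STAGE_PROBS = {"I": 0.47, "II": 0.15, "III": 0.38}


@dataclass(frozen=True)
class SiteSpec:
    """Per-site sample counts for the generator."""

    name: str
    n_cases: int
    n_controls_nodule: int
    n_controls_smoker: int
    smoker_subtype: str = "smoker_no_nodule"

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls_nodule, self.n_controls_smoker) < 0:
            raise ConfigError(f"site {self.name!r}: negative sample count")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls_nodule + self.n_controls_smoker


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration.

    ``disease_markers`` maps analyte index -> delta (case log-mean shift in
    units of the control log-SD, signed).  ``site_artifact_markers`` maps
    analyte index -> per-site offsets (same units, one entry per site, applied
    to both classes).
    """

    sites: tuple[SiteSpec, ...]
    n_analytes: int = 813
    disease_markers: dict[int, float] = field(default_factory=dict)
    site_artifact_markers: dict[int, tuple[float, ...]] = field(default_factory=dict)
    baseline_mu_range: tuple[float, float] = (4.0, 13.2)
    baseline_sigma_range: tuple[float, float] = (0.2, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_analytes < 1:
            raise ConfigError("n_analytes must be >= 1")
        if not self.sites:
            raise ConfigError("at least one site is required")
        overlap = set(self.disease_markers) & set(self.site_artifact_markers)
        if overlap:
            raise ConfigError(
                f"disease and site-artifact marker sets overlap: {sorted(overlap)}"
            )
        for idx in list(self.disease_markers) + list(self.site_artifact_markers):
            if not (0 <= idx < self.n_analytes):
                raise ConfigError(f"marker index {idx} outside [0, {self.n_analytes})")
        for idx, offsets in self.site_artifact_markers.items():
            if len(offsets) != len(self.sites):
                raise ConfigError(
                    f"site-artifact analyte {idx}: {len(offsets)} offsets for "
                    f"{len(self.sites)} sites"
                )
        if self.n_cases_total < 1 or self.n_controls_total < 1:
            raise ConfigError("need at least one case and one control overall")
        lo, hi = self.baseline_sigma_range
        if lo <= 0 or hi < lo:
            raise ConfigError("baseline_sigma_range must be positive and ordered")

    @property
    def n_cases_total(self) -> int:
        return sum(s.n_cases for s in self.sites)

    @property
    def n_controls_total(self) -> int:
        return sum(s.n_controls_nodule + s.n_controls_smoker for s in self.sites)

    @property
    def n_samples(self) -> int:
        return self.n_cases_total + self.n_controls_total


def population_ks(delta: float) -> float:
    """Population KS distance of an equal-variance normal shift of ``delta`` SDs."""
    return float(2.0 * norm.cdf(abs(delta) / 2.0) - 1.0)


def _analyte_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"A{j:0{width}d}" for j in range(n)]


def generate(config: SyntheticConfig) -> tuple[AnalyteMatrix, list[SampleAnnotation]]:
    """Generate a matrix and matching annotations; identical seed, identical output."""
    rng = np.random.default_rng(config.seed)
    p = config.n_analytes
    mu = rng.uniform(*config.baseline_mu_range, size=p)
    sigma = rng.uniform(*config.baseline_sigma_range, size=p)

    delta = np.zeros(p)
    for j, d in config.disease_markers.items():
        delta[j] = d
    site_offsets = np.zeros((len(config.sites), p))
    for j, offsets in config.site_artifact_markers.items():
        site_offsets[:, j] = np.asarray(offsets, dtype=float)

    # sample layout: per site, cases then nodule controls then smoker controls
    rows: list[tuple[int, bool, SiteSpec, str]] = []
    for s_idx, site in enumerate(config.sites):
        rows.extend((s_idx, True, site, "not_applicable") for _ in range(site.n_cases))
        rows.extend(
            (s_idx, False, site, "benign_nodule") for _ in range(site.n_controls_nodule)
        )
        rows.extend(
            (s_idx, False, site, site.smoker_subtype)
            for _ in range(site.n_controls_smoker)
        )
    n = len(rows)

    site_idx = np.array([r[0] for r in rows])
    is_case = np.array([r[1] for r in rows])
    log_values = rng.standard_normal((n, p)) * sigma + mu
    log_values += site_offsets[site_idx] * sigma
    log_values[is_case] += delta * sigma

    width = max(4, len(str(n)))
    sample_ids = [f"S{i:0{width}d}" for i in range(n)]
    barcodes = [f"B{i:0{width}d}" for i in rng.permutation(n)]

    annotations: list[SampleAnnotation] = []
    stage_levels = list(_STAGE_PROBS)
    stage_probs = np.array(list(_STAGE_PROBS.values()))
    stage_probs = stage_probs / stage_probs.sum()
    for i, (s_idx, case, site, subtype) in enumerate(rows):
        age = float(round(min(90.0, max(40.0, rng.normal(62.0, 9.0))), 1))
        smoking = rng.choice(
            ["current", "ex", "never", "unknown"], p=[0.45, 0.45, 0.05, 0.05]
        )
        pack_years = float(round(abs(rng.normal(42.0, 22.0)), 1))
        gold = rng.choice(["0/I", "II", "III/IV", "unknown"], p=[0.55, 0.28, 0.08, 0.09])
        if case:
            stage = str(rng.choice(stage_levels, p=stage_probs))
            histology = str(rng.choice(_HISTOLOGY_LEVELS, p=[0.55, 0.33, 0.02, 0.10]))
        else:
            stage = "not_applicable"
            histology = "unknown"
        annotations.append(
            SampleAnnotation(
                sample_id=sample_ids[i],
                class_label="case" if case else "control",
                site=site.name,
                control_subtype=subtype,
                stage=stage,
                histology=histology,
                age=age,
                sex=str(rng.choice(["male", "female"])),
                smoking_status=str(smoking),
                pack_years=pack_years,
                gold_grade=str(gold),
                barcode=barcodes[i],
            )
        )

    matrix = AnalyteMatrix(sample_ids, _analyte_ids(p), np.exp(log_values))
    return matrix, annotations


def default_study_mimic(
    seed: int = 0,
    n_analytes: int = cohort.N_ANALYTES,
    n_disease_markers: int = 44,
    n_site_artifacts: int = 7,
    delta_range: tuple[float, float] = (0.6, 1.4),
    artifact_amplitude: float = 1.5,
) -> SyntheticConfig:
    """Configuration mimicking the reference study's site composition.

    Four sites with the published case / benign-nodule / smoker control
    counts, 813 analytes, 44 planted disease markers with |delta| drawn
    uniformly from ``delta_range`` (random sign), and 7 site-artifact analytes
    whose per-site offsets are a random permutation of a spread pattern with
    maximum amplitude ``artifact_amplitude`` (in sigma units).
    """
    rng = np.random.default_rng(seed)
    sites = tuple(
        SiteSpec(name, c, b, s, cohort.SITE_SMOKER_SUBTYPE[name])
        for name, (c, b, s) in cohort.SITE_COMPOSITION.items()
    )
    picked = rng.choice(n_analytes, size=n_disease_markers + n_site_artifacts, replace=False)
    disease_idx = np.sort(picked[:n_disease_markers])
    artifact_idx = np.sort(picked[n_disease_markers:])
    lo, hi = delta_range
    deltas = rng.uniform(lo, hi, size=n_disease_markers) * rng.choice(
        [-1.0, 1.0], size=n_disease_markers
    )
    pattern = artifact_amplitude * np.array([-1.0, -1.0 / 3.0, 1.0 / 3.0, 1.0])
    artifacts = {
        int(j): tuple(rng.permutation(pattern)[: len(sites)]) for j in artifact_idx
    }
    return SyntheticConfig(
        sites=sites,
        n_analytes=n_analytes,
        disease_markers={int(j): float(d) for j, d in zip(disease_idx, deltas)},
        site_artifact_markers=artifacts,
        seed=seed,
    )


def training_scale_sites(
    n_cases: int = cohort.TRAINING_CASES,
    n_controls: int = cohort.TRAINING_CONTROLS,
) -> tuple[SiteSpec, ...]:
    """Four sites with case/control counts scaled from the published composition.

    Largest-remainder apportionment of ``n_cases`` over the per-site case
    counts and of ``n_controls`` over the per-site control counts (nodule and
    smoker cells scaled jointly), so totals are exact.
    """
    names = list(cohort.SITE_COMPOSITION)
    cases = _apportion([cohort.SITE_COMPOSITION[s][0] for s in names], n_cases)
    ctrl_cells = []
    for s in names:
        _, b, sm = cohort.SITE_COMPOSITION[s]
        ctrl_cells.extend([b, sm])
    ctrl = _apportion(ctrl_cells, n_controls)
    return tuple(
        SiteSpec(
            name,
            cases[i],
            ctrl[2 * i],
            ctrl[2 * i + 1],
            cohort.SITE_SMOKER_SUBTYPE[name],
        )
        for i, name in enumerate(names)
    )


def _apportion(weights: Sequence[int], total: int) -> list[int]:
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ConfigError("apportionment weights must sum to a positive value")
    quota = weights * total / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = total - int(counts.sum())
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts.tolist()


__all__ = [
    "SiteSpec",
    "SyntheticConfig",
    "generate",
    "default_study_mimic",
    "training_scale_sites",
    "population_ks",
]
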
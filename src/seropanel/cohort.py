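"""Published cohort composition of the reference multi-site NSCLC study.

These printed per-site and per-set counts are the design inputs used both to
scale the synthetic study mimic and for the arithmetic consistency checks in
the acceptance report.  All derived quantities are recomputed from the raw
counts at call time.
"""

from __future__ import annotations

# per-site composition: site -> (cases, benign-nodule controls, smoker controls)
SITE_COMPOSITION: dict[str, tuple[int, int, int]] = {
    "BS": (43, 0, 63),
    "RPCI": (72, 66, 110),
    "NYU": (88, 238, 172),
    "PITT": (88, 261, 125),
}

# smoker controls from NYU and PITT were CT nodule-free; RPCI and BS unknown
SITE_SMOKER_SUBTYPE: dict[str, str] = {
    "BS": "smoker_unknown_nodule",
    "RPCI": "smoker_unknown_nodule",
    "NYU": "smoker_no_nodule",
    "PITT": "smoker_no_nodule",
}

N_ANALYTES = 813

# training / verification split sizes
TRAINING_CASES = 213
TRAINING_CONTROLS = 772
VERIFICATION_CASES = 78
VERIFICATION_CONTROLS = 263

# NSCLC stage counts per set
TRAINING_STAGE = {"I": 99, "II": 32, "III": 82}
VERIFICATION_STAGE = {"I": 38, "II": 11, "III": 27, "not_reported": 2}

# histology counts, training set
TRAINING_HISTOLOGY = {
    "adenocarcinoma": 120,
    "squamous": 71,
    "large_cell": 2,
    "nsclc_nos": 20,
}

# control nodule status, training set
TRAINING_CONTROL_NODULE = {"benign_nodule": 420, "no_nodule": 222, "unknown": 130}


def site_totals() -> dict[str, int]:
    return {s: sum(counts) for s, counts in SITE_COMPOSITION.items()}


def total_samples() -> int:
    """Study size as the sum of the four per-site totals."""
    return sum(site_totals().values())


def total_cases() -> int:
    return sum(c for c, _, _ in SITE_COMPOSITION.values())


def total_controls() -> int:
    return sum(b + s for _, b, s in SITE_COMPOSITION.values())


def training_case_pct() -> float:
    """Percent of training-set individuals that are cases, one decimal."""
    return round(100.0 * TRAINING_CASES / (TRAINING_CASES + TRAINING_CONTROLS), 1)


def stage1_case_pct() -> float:
    """Percent of all cases (training + verification) that are stage I, one decimal."""
    stage1 = TRAINING_STAGE["I"] + VERIFICATION_STAGE["I"]
    return round(100.0 * stage1 / (TRAINING_CASES + VERIFICATION_CASES), 1)


def training_adenocarcinoma_pct() -> float:
    """Percent of training-set cases with adenocarcinoma histology, one decimal."""
    return round(100.0 * TRAINING_HISTOLOGY["adenocarcinoma"] / TRAINING_CASES, 1)


def total_measurements() -> int:
    """Individual protein measurements: analytes per sample times samples."""
    return N_ANALYTES * total_samples()


def training_benign_nodule_control_pct() -> float:
    """Percent of training-set controls with a benign nodule, one decimal."""
    return round(
        100.0 * TRAINING_CONTROL_NODULE["benign_nodule"] / TRAINING_CONTROLS, 1
    )


__all__ = [
    "SITE_COMPOSITION",
    "SITE_SMOKER_SUBTYPE",
    "N_ANALYTES",
    "TRAINING_CASES",
    "TRAINING_CONTROLS",
    "VERIFICATION_CASES",
    "VERIFICATION_CONTROLS",
    "TRAINING_STAGE",
    "VERIFICATION_STAGE",
    "TRAINING_HISTOLOGY",
    "TRAINING_CONTROL_NODULE",
    "site_totals",
    "total_samples",
    "total_cases",
    "total_controls",
    "training_case_pct",
    "stage1_case_pct",
    "training_adenocarcinoma_pct",
    "total_measurements",
    "training_benign_nodule_control_pct",
]
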
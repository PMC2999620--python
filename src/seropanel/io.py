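"""Shared data model and tab-separated I/O for the analyte matrix and annotations.

The interchange formats are deliberately plain:

* matrix file — TSV, header row of analyte ids, leading column ``sample_id``,
  strictly positive numeric body (relative fluorescence units);
* annotation file — TSV with the fixed header
  ``sample_id class_label site control_subtype stage histology age sex
  smoking_status pack_years gold_grade barcode``, unknowns encoded as ``NA``;
* blinding key file — TSV with columns ``barcode``, ``class_label``.

Floats are written with :func:`repr` so write/read round trips are bit-stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationFormatError, ConfigError, MatrixFormatError

NA_TOKEN = "NA"

CLASS_LEVELS = ("case", "control")
CONTROL_SUBTYPE_LEVELS = (
    "benign_nodule",
    "smoker_no_nodule",
    "smoker_unknown_nodule",
    "not_applicable",
)
STAGE_LEVELS = ("I", "II", "III", "unknown", "not_applicable")
SEX_LEVELS = ("male", "female", "unknown")
SMOKING_LEVELS = ("current", "ex", "never", "unknown")
GOLD_LEVELS = ("0/I", "II", "III/IV", "unknown")

ANNOTATION_COLUMNS = (
    "sample_id",
    "class_label",
    "site",
    "control_subtype",
    "stage",
    "histology",
    "age",
    "sex",
    "smoking_status",
    "pack_years",
    "gold_grade",
    "barcode",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AnalyteMatrix:
    """Samples x analytes grid of strictly positive RFU values."""

    sample_ids: list[str]
    analyte_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.analyte_ids = [str(a) for a in self.analyte_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixFormatError("matrix values must be two-dimensional")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise MatrixFormatError(
                f"row count {n} does not match {len(self.sample_ids)} sample ids"
            )
        if p != len(self.analyte_ids):
            raise MatrixFormatError(
                f"column count {p} does not match {len(self.analyte_ids)} analyte ids"
            )
        for label, ids in (("sample", self.sample_ids), ("analyte", self.analyte_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
                raise MatrixFormatError(f"duplicate {label} id {dup!r}")
        bad = ~(np.isfinite(self.values) & (self.values > 0))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise MatrixFormatError(
                f"non-positive or non-finite value {self.values[i, j]!r} at "
                f"sample {self.sample_ids[i]!r}, analyte {self.analyte_ids[j]!r}"
            )
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._analyte_index = {a: j for j, a in enumerate(self.analyte_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_analytes(self) -> int:
        return len(self.analyte_ids)

    def analyte_index(self, analyte_id: str) -> int:
        try:
            return self._analyte_index[analyte_id]
        except KeyError:
            raise KeyError(f"unknown analyte id {analyte_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def column(self, analyte_id: str) -> np.ndarray:
        return self.values[:, self.analyte_index(analyte_id)]

    def row(self, sample_id: str) -> dict[str, float]:
        v = self.values[self.sample_index(sample_id)]
        return dict(zip(self.analyte_ids, v.tolist()))

    def subset_samples(self, mask: np.ndarray) -> "AnalyteMatrix":
        mask = np.asarray(mask, dtype=bool)
        ids = [s for s, keep in zip(self.sample_ids, mask) if keep]
        return AnalyteMatrix(ids, list(self.analyte_ids), self.values[mask])

    def subset_analytes(self, analyte_ids: Sequence[str]) -> "AnalyteMatrix":
        idx = [self.analyte_index(a) for a in analyte_ids]
        return AnalyteMatrix(list(self.sample_ids), list(analyte_ids), self.values[:, idx])


@dataclass(frozen=True)
class SampleAnnotation:
    """Clinical/site/class metadata for one serum sample."""

    sample_id: str
    class_label: str
    site: str
    control_subtype: str = "not_applicable"
    stage: str = "not_applicable"
    histology: str = "unknown"
    age: float | None = None
    sex: str = "unknown"
    smoking_status: str = "unknown"
    pack_years: float | None = None
    gold_grade: str = "unknown"
    barcode: str = ""

    def __post_init__(self) -> None:
        _check_level("class_label", self.class_label, CLASS_LEVELS, self.sample_id)
        _check_level("control_subtype", self.control_subtype, CONTROL_SUBTYPE_LEVELS, self.sample_id)
        _check_level("stage", self.stage, STAGE_LEVELS, self.sample_id)
        _check_level("sex", self.sex, SEX_LEVELS, self.sample_id)
        _check_level("smoking_status", self.smoking_status, SMOKING_LEVELS, self.sample_id)
        _check_level("gold_grade", self.gold_grade, GOLD_LEVELS, self.sample_id)
        if not self.site:
            raise AnnotationFormatError(f"sample {self.sample_id!r}: empty site")
        if self.class_label == "case" and self.control_subtype != "not_applicable":
            raise AnnotationFormatError(
                f"sample {self.sample_id!r}: a case must have control_subtype "
                f"'not_applicable', got {self.control_subtype!r}"
            )
        if self.class_label == "control" and self.stage != "not_applicable":
            raise AnnotationFormatError(
                f"sample {self.sample_id!r}: a control must have stage "
                f"'not_applicable', got {self.stage!r}"
            )
        if self.pack_years is not None and self.pack_years < 0:
            raise AnnotationFormatError(
                f"sample {self.sample_id!r}: negative pack_years {self.pack_years}"
            )

    @property
    def is_case(self) -> bool:
        return self.class_label == "case"


@dataclass(frozen=True)
class BlindingKey:
    """Barcode -> class label map, held apart from annotations.

    Training operations never accept this type; only
    :func:`seropanel.pipeline.verify_blinded` reads it.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for barcode, label in self.mapping.items():
            if label not in CLASS_LEVELS:
                raise AnnotationFormatError(
                    f"blinding key barcode {barcode!r}: unknown class {label!r}"
                )

    def class_of(self, barcode: str) -> str:
        return self.mapping[barcode]


def _check_level(name: str, value: str, levels: tuple[str, ...], sample_id: str) -> None:
    if value not in levels:
        raise AnnotationFormatError(
            f"sample {sample_id!r}: unknown {name} level {value!r} "
            f"(allowed: {', '.join(levels)})"
        )


# ---------------------------------------------------------------------------
# mask helpers used throughout the pipeline
# ---------------------------------------------------------------------------


def case_mask(annotations: Sequence[SampleAnnotation]) -> np.ndarray:
    return np.array([a.is_case for a in annotations], dtype=bool)


def control_mask(annotations: Sequence[SampleAnnotation]) -> np.ndarray:
    return ~case_mask(annotations)


def sites_of(annotations: Sequence[SampleAnnotation]) -> np.ndarray:
    return np.array([a.site for a in annotations], dtype=object)


def check_matrix_annotations(
    matrix: AnalyteMatrix, annotations: Sequence[SampleAnnotation]
) -> None:
    """Every matrix sample must appear exactly once, in order, in the annotations."""
    ann_ids = [a.sample_id for a in annotations]
    if ann_ids != list(matrix.sample_ids):
        raise AnnotationFormatError(
            "annotation sample ids do not match matrix sample ids (order and identity)"
        )


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------


def read_matrix(path) -> AnalyteMatrix:
    """Read a TSV analyte matrix (header of analyte ids, leading sample_id column)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    sample_ids = [str(s) for s in df.index]
    analyte_ids = [str(a) for a in df.columns]
    values = np.empty((len(sample_ids), len(analyte_ids)), dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # numpy's parser is correctly rounded (pandas' to_numeric is not)
            values[:, j] = df[col].to_numpy(dtype=str).astype(float)
        except ValueError:
            for i, token in enumerate(df[col]):
                try:
                    float(token)
                except ValueError:
                    raise MatrixFormatError(
                        f"non-numeric value {token!r} at sample {sample_ids[i]!r}, "
                        f"analyte {analyte_ids[j]!r}"
                    ) from None
            raise
    return AnalyteMatrix(sample_ids, analyte_ids, values)


def write_matrix(matrix: AnalyteMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(matrix.analyte_ids) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.values):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def _parse_optional_float(token: str, column: str, sample_id: str) -> float | None:
    if token == NA_TOKEN or token == "":
        return None
    try:
        return float(token)
    except ValueError:
        raise AnnotationFormatError(
            f"sample {sample_id!r}: non-numeric {column} {token!r}"
        ) from None


def read_annotations(path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != list(ANNOTATION_COLUMNS):
        raise AnnotationFormatError(
            f"annotation header must be {list(ANNOTATION_COLUMNS)}, got {list(df.columns)}"
        )
    records: list[SampleAnnotation] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        if not sid or sid == NA_TOKEN:
            raise AnnotationFormatError("missing sample_id in annotation row")
        if sid in seen:
            raise AnnotationFormatError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
        records.append(
            SampleAnnotation(
                sample_id=sid,
                class_label=str(row.class_label),
                site=str(row.site),
                control_subtype=str(row.control_subtype),
                stage=str(row.stage),
                histology=str(row.histology) if row.histology != NA_TOKEN else "unknown",
                age=_parse_optional_float(str(row.age), "age", sid),
                sex=str(row.sex) if row.sex != NA_TOKEN else "unknown",
                smoking_status=str(row.smoking_status) if row.smoking_status != NA_TOKEN else "unknown",
                pack_years=_parse_optional_float(str(row.pack_years), "pack_years", sid),
                gold_grade=str(row.gold_grade) if row.gold_grade != NA_TOKEN else "unknown",
                barcode=str(row.barcode) if row.barcode != NA_TOKEN else "",
            )
        )
    return records


def write_annotations(annotations: Iterable[SampleAnnotation], path) -> None:
    def fmt(value) -> str:
        if value is None or value == "":
            return NA_TOKEN
        if isinstance(value, float):
            return repr(value)
        return str(value)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for a in annotations:
            fh.write(
                "\t".join(
                    fmt(getattr(a, col)) for col in ANNOTATION_COLUMNS
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# blinding key I/O
# ---------------------------------------------------------------------------


def read_blinding_key(path) -> BlindingKey:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != ["barcode", "class_label"]:
        raise AnnotationFormatError(
            f"blinding key header must be ['barcode', 'class_label'], got {list(df.columns)}"
        )
    mapping: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.barcode in mapping:
            raise AnnotationFormatError(f"duplicate barcode {row.barcode!r}")
        mapping[str(row.barcode)] = str(row.class_label)
    return BlindingKey(mapping)


def write_blinding_key(key: BlindingKey, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("barcode\tclass_label\n")
        for barcode in sorted(key.mapping):
            fh.write(f"{barcode}\t{key.mapping[barcode]}\n")


def build_blinding_key(
    annotations: Sequence[SampleAnnotation], split: Mapping[str, str]
) -> BlindingKey:
    """Blinding key covering exactly the verification samples of a split."""
    mapping = {
        a.barcode: a.class_label
        for a in annotations
        if split.get(a.sample_id) == "verification"
    }
    return BlindingKey(mapping)


# ---------------------------------------------------------------------------
# sample splitting
# ---------------------------------------------------------------------------


def split_samples(
    annotations: Sequence[SampleAnnotation],
    verification_fraction: float = 0.25,
    seed: int = 0,
) -> dict[str, str]:
    """Randomly partition samples into training / verification roles.

    The realized verification count is ``round(fraction * n)`` (half away
    from zero).  Simple random sampling, no stratification; seed-deterministic.
    """
    if not (0.0 < verification_fraction < 1.0):
        raise ConfigError(
            f"verification_fraction must be in (0, 1), got {verification_fraction}"
        )
    ids = [a.sample_id for a in annotations]
    n = len(ids)
    n_verif = int(math.floor(verification_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    verification = {ids[i] for i in order[:n_verif]}
    return {
        sid: ("verification" if sid in verification else "training") for sid in ids
    }


def split_mask(
    annotations: Sequence[SampleAnnotation], split: Mapping[str, str], role: str
) -> np.ndarray:
    return np.array([split[a.sample_id] == role for a in annotations], dtype=bool)


__all__ = [
    "AnalyteMatrix",
    "SampleAnnotation",
    "BlindingKey",
    "NA_TOKEN",
    "ANNOTATION_COLUMNS",
    "CLASS_LEVELS",
    "CONTROL_SUBTYPE_LEVELS",
    "STAGE_LEVELS",
    "SEX_LEVELS",
    "SMOKING_LEVELS",
    "GOLD_LEVELS",
    "read_matrix",
    "write_matrix",
    "read_annotations",
    "write_annotations",
    "read_blinding_key",
    "write_blinding_key",
    "build_blinding_key",
    "split_samples",
    "split_mask",
    "case_mask",
    "control_mask",
    "sites_of",
    "check_matrix_annotations",
]
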
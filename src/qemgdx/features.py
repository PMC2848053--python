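"""Feature definitions and tabular I/O for quantitative EMG data.

A decomposed needle-EMG recording yields motor unit potential trains
(MUPTs), each summarised by 15 quantitative features describing the motor
unit potential shape (amplitude, duration, phases, turns, macro measures)
and the motor unit firing behaviour (inter-discharge interval statistics
and firing rates).  Amplitude- and area-like features arise from a
multiplicative combination of fibre size, fibre count and electrode
distance, so their raw distributions are strongly right-skewed; those five
features are natural-log transformed so that a per-class Gaussian model is
a reasonable description.

All MUPTs recorded from one muscle of one subject on one occasion form a
*muscle study* — the atomic unit for cross-validation splitting and for
muscle-level aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NORMATIVE",
    "NSAP",
    "CLASS_LABELS",
    "FeatureDef",
    "MUPTRecord",
    "MuscleStudy",
    "StudyCollection",
    "FeatureTableError",
    "MissingColumnError",
    "UnknownClassLabelError",
    "EmptyTableError",
    "InconsistentStudyClassError",
    "TransformDomainError",
    "default_feature_set",
    "normalize_class_label",
    "apply_transforms",
    "invert_transforms",
    "load_feature_table",
    "write_feature_table",
]

NORMATIVE = "Normative"
NSAP = "NSAP"
#: Canonical class order; "first-listed" tie-breaks throughout refer to it.
CLASS_LABELS = (NORMATIVE, NSAP)

# Accepted spellings for class labels in input tables (case-insensitive).
_CLASS_ALIASES = {
    "normative": NORMATIVE,
    "control": NORMATIVE,
    "normal": NORMATIVE,
    "nsap": NSAP,
}


class FeatureTableError(ValueError):
    """Base class for malformed feature-table input."""


class MissingColumnError(FeatureTableError):
    """A required column is absent from the table header."""


class UnknownClassLabelError(FeatureTableError):
    """A class label is not a recognised Normative/NSAP spelling."""


class EmptyTableError(FeatureTableError):
    """The table contains no data rows."""


class InconsistentStudyClassError(FeatureTableError):
    """Rows sharing a study id carry conflicting class labels."""


class TransformDomainError(ValueError):
    """A log-transformed feature received a non-positive raw value."""


@dataclass(frozen=True)
class FeatureDef:
    """One quantitative EMG feature: display name, table column, units, transform."""

    name: str
    abbreviation: str
    units: str
    log_transformed: bool


# name, column abbreviation, units (transformed scale where log applies), log flag
_FEATURE_TABLE = (
    ("Amplitude", "Ampl", "ln(μV)", True),
    ("Duration", "Duration", "μs", False),
    ("Phases", "Phases", "", False),
    ("Turns", "Turns", "", False),
    ("Area/Amplitude Ratio", "AAR", "ln(ms)", True),
    ("Macro Amplitude", "MacAmpl", "ln(μV)", True),
    ("Macro Negative Peak Area", "MacNPkArea", "ln(μV·ms)", True),
    ("Macro Neg. Peak Amplitude", "MacNPkAmpl", "ln(μV)", True),
    ("Macro Negative Peak Duration", "MacNPkDur", "ms", False),
    ("Inter-Discharge Interval Mean", "IDImean", "ms", False),
    ("IDI Standard Deviation", "IDIsd", "", False),
    ("IDI Covariance", "IDIcov", "", False),
    ("Inter-Discharge Rate", "IDRate", "pps", False),
    ("Firing Rate", "FR", "pps", False),
    ("Firing Rate Mean Consecutive Difference", "FRMCD", "pps", False),
)


def default_feature_set() -> list[FeatureDef]:
    """The standard 15-feature set, 5 of which are natural-log transformed."""
    return [FeatureDef(*row) for row in _FEATURE_TABLE]


def normalize_class_label(label: str) -> str:
    """Map an input class spelling to a canonical label, or raise.

    Matching is case-insensitive; ``control`` and ``normal`` are accepted
    aliases for ``Normative``.  Anything unrecognised raises rather than
    guessing.
    """
    key = str(label).strip().lower()
    try:
        return _CLASS_ALIASES[key]
    except KeyError:
        raise UnknownClassLabelError(
            f"unknown class label {label!r}; expected one of "
            f"{sorted(set(_CLASS_ALIASES))}"
        ) from None


def _log_mask(feature_set: Sequence[FeatureDef]) -> np.ndarray:
    return np.array([f.log_transformed for f in feature_set], dtype=bool)


def apply_transforms(
    raw_values: Sequence[float] | np.ndarray,
    feature_set: Sequence[FeatureDef] | None = None,
) -> np.ndarray:
    """Map a raw-scale feature vector (or matrix) onto the transformed scale.

    Log-flagged features are replaced by their natural logarithm; all other
    features pass through unchanged.  Not idempotent: the caller tracks
    which scale a vector is on.

    Raises
    ------
    TransformDomainError
        If a log-flagged feature holds a non-positive value (named in the
        message).
    """
    if feature_set is None:
        feature_set = default_feature_set()
    values = np.asarray(raw_values, dtype=float)
    if values.shape[-1] != len(feature_set):
        raise ValueError(
            f"expected {len(feature_set)} features, got {values.shape[-1]}"
        )
    mask = _log_mask(feature_set)
    logged = values[..., mask]
    if np.any(logged <= 0):
        bad = np.asarray(logged <= 0).any(axis=tuple(range(logged.ndim - 1)))
        names = [f.abbreviation for f, m in zip(feature_set, mask) if m]
        offending = [n for n, b in zip(names, np.atleast_1d(bad)) if b]
        raise TransformDomainError(
            f"non-positive value for log-transformed feature(s) {offending}"
        )
    out = values.copy()
    out[..., mask] = np.log(logged)
    return out


def invert_transforms(
    values: Sequence[float] | np.ndarray,
    feature_set: Sequence[FeatureDef] | None = None,
) -> np.ndarray:
    """Inverse of :func:`apply_transforms`: exponentiate log-flagged features."""
    if feature_set is None:
        feature_set = default_feature_set()
    arr = np.asarray(values, dtype=float).copy()
    mask = _log_mask(feature_set)
    arr[..., mask] = np.exp(arr[..., mask])
    return arr


@dataclass
class MUPTRecord:
    """One motor unit potential train: a feature vector with provenance.

    ``features`` is on the transformed scale (the scale on which all class
    models operate).
    """

    study_id: str
    true_class: str
    features: np.ndarray

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        if feats.ndim != 1:
            raise ValueError("features must be a 1-D vector")
        if not np.all(np.isfinite(feats)):
            raise ValueError(
                f"non-finite feature value in record from study {self.study_id!r}"
            )
        if self.true_class not in CLASS_LABELS:
            raise UnknownClassLabelError(
                f"true_class must be one of {CLASS_LABELS}, got {self.true_class!r}"
            )
        self.features = feats


@dataclass
class MuscleStudy:
    """All MUPTs from one muscle on one occasion; unit of CV and aggregation."""

    study_id: str
    true_class: str
    records: list[MUPTRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"muscle study {self.study_id!r} has no records")
        for rec in self.records:
            if rec.study_id != self.study_id:
                raise ValueError(
                    f"record study_id {rec.study_id!r} != study {self.study_id!r}"
                )
            if rec.true_class != self.true_class:
                raise InconsistentStudyClassError(
                    f"study {self.study_id!r}: record class {rec.true_class!r} "
                    f"conflicts with study class {self.true_class!r}"
                )
        lengths = {rec.features.size for rec in self.records}
        if len(lengths) != 1:
            raise ValueError(f"study {self.study_id!r}: mixed feature lengths")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def feature_matrix(self) -> np.ndarray:
        """(n_records, d) matrix of feature vectors, transformed scale."""
        return np.vstack([rec.features for rec in self.records])


@dataclass
class StudyCollection:
    """A set of muscle studies sharing one feature set."""

    studies: list[MuscleStudy]
    feature_set: list[FeatureDef] = field(default_factory=default_feature_set)

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate study ids: {dupes}")
        d = len(self.feature_set)
        for study in self.studies:
            if study.records[0].features.size != d:
                raise ValueError(
                    f"study {study.study_id!r} has "
                    f"{study.records[0].features.size} features, expected {d}"
                )
        abbrevs = [f.abbreviation for f in self.feature_set]
        if len(set(abbrevs)) != len(abbrevs):
            raise ValueError("feature abbreviations must be unique")

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_records(self) -> int:
        return sum(s.n_records for s in self.studies)

    def iter_records(self) -> Iterable[MUPTRecord]:
        for study in self.studies:
            yield from study.records

    def studies_of(self, class_label: str) -> list[MuscleStudy]:
        return [s for s in self.studies if s.true_class == class_label]

    def class_matrix(self, class_label: str) -> np.ndarray:
        """Stacked feature matrix of every record with the given true class."""
        mats = [s.feature_matrix for s in self.studies_of(class_label)]
        if not mats:
            raise ValueError(f"no studies of class {class_label!r}")
        return np.vstack(mats)

    def to_frame(self, scale: str = "transformed") -> pd.DataFrame:
        """Flatten to one row per MUPT; ``scale`` is ``transformed`` or ``raw``."""
        if scale not in ("transformed", "raw"):
            raise ValueError(f"scale must be 'transformed' or 'raw', got {scale!r}")
        abbrevs = [f.abbreviation for f in self.feature_set]
        ids, classes, mats = [], [], []
        for study in self.studies:
            mat = study.feature_matrix
            if scale == "raw":
                mat = invert_transforms(mat, self.feature_set)
            ids.extend([study.study_id] * study.n_records)
            classes.extend([study.true_class] * study.n_records)
            mats.append(mat)
        frame = pd.DataFrame(np.vstack(mats), columns=abbrevs)
        frame.insert(0, "class", classes)
        frame.insert(0, "study_id", ids)
        return frame


def _sep_for(source) -> str:
    name = getattr(source, "name", source)
    return "\t" if str(name).lower().endswith(".tsv") else ","


def load_feature_table(
    source: str | Path | IO[str],
    feature_set: Sequence[FeatureDef] | None = None,
    scale: str = "raw",
) -> StudyCollection:
    """Read a per-MUPT feature table (CSV, or TSV by ``.tsv`` extension).

    The header must contain ``study_id``, ``class`` and all 15 feature
    abbreviations; rows are grouped by study id in order of first
    appearance.  ``scale`` declares the scale of the incoming values:
    ``raw`` (physical units; log transforms are applied, the default for
    clinical exports) or ``transformed`` (values used as-is).
    """
    if scale not in ("raw", "transformed"):
        raise ValueError(f"scale must be 'raw' or 'transformed', got {scale!r}")
    feature_set = list(feature_set) if feature_set is not None else default_feature_set()
    try:
        # round_trip parsing: written tables reload bit-identically
        df = pd.read_csv(source, sep=_sep_for(source), float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyTableError("feature table is empty") from None

    required = ["study_id", "class"] + [f.abbreviation for f in feature_set]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing required column(s): {missing}")
    if len(df) == 0:
        raise EmptyTableError("feature table has a header but no data rows")

    df = df.copy()
    df["class"] = df["class"].map(normalize_class_label)

    abbrevs = [f.abbreviation for f in feature_set]
    studies: list[MuscleStudy] = []
    for study_id, group in df.groupby("study_id", sort=False):
        classes = group["class"].unique()
        if len(classes) > 1:
            raise InconsistentStudyClassError(
                f"study {study_id!r} carries conflicting class labels: "
                f"{sorted(classes)}"
            )
        values = group[abbrevs].to_numpy(dtype=float)
        if scale == "raw":
            values = apply_transforms(values, feature_set)
        records = [
            MUPTRecord(str(study_id), classes[0], row) for row in values
        ]
        studies.append(MuscleStudy(str(study_id), classes[0], records))
    return StudyCollection(studies, feature_set)


def write_feature_table(
    collection: StudyCollection,
    sink: str | Path | IO[str],
    scale: str = "transformed",
) -> None:
    """Write a collection as CSV/TSV; default transformed scale round-trips
    exactly with ``load_feature_table(..., scale="transformed")``."""
    abbrevs = [f.abbreviation for f in collection.feature_set]
    if collection.studies:
        df = collection.to_frame(scale=scale)
    else:
        df = pd.DataFrame(columns=["study_id", "class", *abbrevs])
    # repr round-trips float64 exactly; pandas' default float writer does not
    df.to_csv(
        sink, sep=_sep_for(sink), index=False,
        float_format=lambda v: repr(float(v)),
    )
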
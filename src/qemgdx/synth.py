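"""Synthetic muscle-study generator.

Emulates the statistical structure of a two-class quantitative-EMG data
set so the whole pipeline is testable without clinical recordings:

* two classes (Normative, NSAP) whose transformed features are
  approximately Gaussian, with per-class per-feature means and SDs
  defaulting to published reference statistics for the 15-feature set on
  the transformed scale;
* MUPTs grouped into muscle studies (default 30 MUPTs per study, the
  acquisition floor of the emulated protocol);
* class imbalance (default 40 normative vs 17 NSAP studies);
* variable involvement: each MUPT of an NSAP study is independently drawn
  from the *normative* distribution with probability ``contamination``,
  modelling the motor units an involving process has left untouched.  The
  study keeps its NSAP label regardless — there is no MUPT-level gold
  standard.

Covariance is diagonal by default (the reference statistics carry no
covariances); an optional constant inter-feature correlation exercises
full-covariance code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .features import (
    CLASS_LABELS,
    NORMATIVE,
    NSAP,
    FeatureDef,
    MUPTRecord,
    MuscleStudy,
    StudyCollection,
    default_feature_set,
)

__all__ = [
    "GeneratorConfig",
    "table4_defaults",
    "generate_study",
    "generate_collection",
    "load_config",
    "REFERENCE_MEANS",
    "REFERENCE_SDS",
]

# Published per-class reference statistics on the transformed scale:
# feature abbreviation -> (mean, SD), where the SD is the mean within-fold
# per-feature standard deviation.
REFERENCE_MEANS: dict[str, dict[str, float]] = {
    NORMATIVE: {
        "Ampl": 5.923, "Duration": 9.742, "Phases": 2.570, "Turns": 3.381,
        "AAR": 0.237, "MacAmpl": 4.187, "MacNPkArea": 5.882,
        "MacNPkAmpl": 3.656, "MacNPkDur": 25.516, "IDImean": 69.881,
        "IDIsd": 9.500, "IDIcov": 0.138, "IDRate": 58.552, "FR": 14.873,
        "FRMCD": 0.192,
    },
    NSAP: {
        "Ampl": 5.883, "Duration": 9.190, "Phases": 2.767, "Turns": 3.101,
        "AAR": 0.333, "MacAmpl": 4.018, "MacNPkArea": 5.439,
        "MacNPkAmpl": 3.432, "MacNPkDur": 17.745, "IDImean": 72.858,
        "IDIsd": 8.265, "IDIcov": 0.112, "IDRate": 54.498, "FR": 14.292,
        "FRMCD": 0.147,
    },
}

REFERENCE_SDS: dict[str, dict[str, float]] = {
    NORMATIVE: {
        "Ampl": 0.555, "Duration": 4.861, "Phases": 0.923, "Turns": 1.658,
        "AAR": 0.393, "MacAmpl": 0.766, "MacNPkArea": 0.936,
        "MacNPkAmpl": 0.738, "MacNPkDur": 13.701, "IDImean": 14.657,
        "IDIsd": 4.293, "IDIcov": 0.056, "IDRate": 22.901, "FR": 2.880,
        "FRMCD": 0.111,
    },
    NSAP: {
        "Ampl": 0.485, "Duration": 2.877, "Phases": 0.925, "Turns": 1.462,
        "AAR": 0.362, "MacAmpl": 0.605, "MacNPkArea": 0.724,
        "MacNPkAmpl": 0.651, "MacNPkDur": 5.753, "IDImean": 15.857,
        "IDIsd": 5.259, "IDIcov": 0.053, "IDRate": 18.650, "FR": 2.802,
        "FRMCD": 0.095,
    },
}


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic generation.

    ``class_means``/``class_sds`` map class label → length-d vector aligned
    with ``feature_set``; ``rho`` is an optional constant inter-feature
    correlation in [0, 1); ``contamination`` is the probability that a
    MUPT in an NSAP study follows the normative distribution.
    """

    class_means: dict[str, np.ndarray]
    class_sds: dict[str, np.ndarray]
    feature_set: list[FeatureDef] = field(default_factory=default_feature_set)
    rho: float = 0.0
    n_normative: int = 40
    n_nsap: int = 17
    mupts_per_study: int = 30
    contamination: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        d = len(self.feature_set)
        for label in CLASS_LABELS:
            if label not in self.class_means or label not in self.class_sds:
                raise ValueError(f"missing mean/SD vectors for class {label!r}")
            self.class_means[label] = np.asarray(
                self.class_means[label], dtype=float
            )
            self.class_sds[label] = np.asarray(self.class_sds[label], dtype=float)
            if self.class_means[label].shape != (d,):
                raise ValueError(f"mean vector for {label!r} must have length {d}")
            if self.class_sds[label].shape != (d,):
                raise ValueError(f"SD vector for {label!r} must have length {d}")
            if np.any(self.class_sds[label] <= 0):
                raise ValueError(f"SDs for {label!r} must be strictly positive")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError(
                f"contamination must lie in [0, 1], got {self.contamination}"
            )
        if self.mupts_per_study < 1:
            raise ValueError("mupts_per_study must be at least 1")
        if self.n_normative < 0 or self.n_nsap < 0:
            raise ValueError("study counts must be non-negative")

    def covariance(self, class_label: str) -> np.ndarray:
        """Per-class covariance: diagonal, or constant-correlation filled."""
        sd = self.class_sds[class_label]
        d = sd.size
        corr = np.full((d, d), self.rho)
        np.fill_diagonal(corr, 1.0)
        return corr * np.outer(sd, sd)


def table4_defaults(**overrides) -> GeneratorConfig:
    """Default configuration from the published reference statistics.

    Keyword overrides are applied on top (e.g. ``contamination=0.0``,
    ``n_normative=100``).
    """
    feature_set = default_feature_set()
    abbrevs = [f.abbreviation for f in feature_set]
    config = GeneratorConfig(
        class_means={
            lab: np.array([REFERENCE_MEANS[lab][a] for a in abbrevs])
            for lab in CLASS_LABELS
        },
        class_sds={
            lab: np.array([REFERENCE_SDS[lab][a] for a in abbrevs])
            for lab in CLASS_LABELS
        },
        feature_set=feature_set,
    )
    return replace(config, **overrides) if overrides else config


def _chol(config: GeneratorConfig, class_label: str) -> np.ndarray:
    sd = config.class_sds[class_label]
    if config.rho == 0.0:
        return np.diag(sd)
    return np.linalg.cholesky(config.covariance(class_label))


def _draw(
    config: GeneratorConfig, class_label: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    z = rng.standard_normal((n, len(config.feature_set)))
    return config.class_means[class_label] + z @ _chol(config, class_label).T


def generate_study(
    config: GeneratorConfig,
    class_label: str,
    rng: np.random.Generator,
    study_id: str = "S0",
) -> MuscleStudy:
    """Generate one muscle study on the transformed scale.

    A normative study draws every MUPT i.i.d. from the normative Gaussian.
    An NSAP study draws each MUPT from the normative Gaussian with
    probability ``contamination`` and from the NSAP Gaussian otherwise;
    the study-level true class stays NSAP either way.
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {class_label!r}")
    n = config.mupts_per_study
    if class_label == NSAP and config.contamination > 0.0:
        from_normative = rng.random(n) < config.contamination
        values = _draw(config, NSAP, n, rng)
        n_contam = int(from_normative.sum())
        if n_contam:
            values[from_normative] = _draw(config, NORMATIVE, n_contam, rng)
    else:
        values = _draw(config, class_label, n, rng)
    records = [MUPTRecord(study_id, class_label, row) for row in values]
    return MuscleStudy(study_id, class_label, records)


def generate_collection(
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> StudyCollection:
    """Generate the configured numbers of studies per class, unique ids.

    Deterministic given ``config.seed`` (or a caller-supplied ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    studies: list[MuscleStudy] = []
    for label, count, prefix in (
        (NORMATIVE, config.n_normative, "NORM"),
        (NSAP, config.n_nsap, "NSAP"),
    ):
        for i in range(count):
            sid = f"{prefix}{i + 1:03d}"
            studies.append(generate_study(config, label, rng, study_id=sid))
    return StudyCollection(studies, config.feature_set)


def load_config(path: str | Path, **overrides) -> GeneratorConfig:
    """Build a GeneratorConfig from a YAML file layered over the defaults.

    Recognised keys: ``n_normative``, ``n_nsap``, ``mupts_per_study``,
    ``contamination``, ``rho``, ``seed``, and optional ``means``/``sds``
    mappings of class label → {feature abbreviation: value} partial
    overrides.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw: Mapping = yaml.safe_load(fh) or {}
    scalar_keys = (
        "n_normative", "n_nsap", "mupts_per_study", "contamination",
        "rho", "seed",
    )
    kwargs = {k: raw[k] for k in scalar_keys if k in raw}
    kwargs.update(overrides)
    config = table4_defaults(**kwargs)
    abbrevs = [f.abbreviation for f in config.feature_set]
    for yaml_key, target in (("means", config.class_means), ("sds", config.class_sds)):
        for label, mapping in (raw.get(yaml_key) or {}).items():
            if label not in CLASS_LABELS:
                raise ValueError(f"unknown class {label!r} in {yaml_key}")
            vec = target[label].copy()
            for abbrev, value in mapping.items():
                if abbrev not in abbrevs:
                    raise ValueError(f"unknown feature {abbrev!r} in {yaml_key}")
                vec[abbrevs.index(abbrev)] = float(value)
            target[label] = vec
    # re-validate after overrides
    return GeneratorConfig(
        class_means=config.class_means,
        class_sds=config.class_sds,
        feature_set=config.feature_set,
        rho=config.rho,
        n_normative=config.n_normative,
        n_nsap=config.n_nsap,
        mupts_per_study=config.mupts_per_study,
        contamination=config.contamination,
        seed=config.seed,
    )
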
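"""Normal-density discriminant function (NDDF) for single MUPTs.

Each class ω_k (Normative or NSAP) is modelled as a multivariate Gaussian
with mean vector m_k and full covariance matrix S_k, estimated from the
pooled training MUPTs of that class.  The minimum-error-rate discriminant
for a feature vector x is, up to a class-independent constant,

    δ_k(x) = −½ (x − m_k)ᵀ S_k⁻¹ (x − m_k) − ½ ln|S_k| + ln P(ω_k)

i.e. the log of the prior-weighted class-conditional normal density with
the (2π)^{d/2} normalisation dropped (it cancels across classes).  The
quadratic form inside δ is the squared Mahalanobis distance

    r_k(x) = sqrt((x − m_k)ᵀ S_k⁻¹ (x − m_k)),

the distance from the class mean in units of standard deviation.  With
equal priors and equal covariance determinants, maximising δ is the same
as minimising r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .features import MUPTRecord

__all__ = [
    "ClassModel",
    "DiscriminantScores",
    "ModelEstimationError",
    "fit_class_model",
    "log_discriminant",
    "mahalanobis",
    "classify_mupt",
    "RIDGE_EPS",
]

logger = logging.getLogger(__name__)

#: Relative ridge added to a covariance that is not positive definite.
RIDGE_EPS = 1e-6


class ModelEstimationError(ValueError):
    """Raised when a class model cannot be estimated from the given records."""


@dataclass
class ClassModel:
    """Fitted Gaussian model of one class: mean, covariance, prior.

    The covariance must be symmetric positive definite on construction;
    :func:`fit_class_model` regularises a degenerate sample covariance
    before building the model.  A Cholesky factor and ln|S| are cached.
    """

    class_label: str
    mean: np.ndarray
    cov: np.ndarray
    prior: float
    n_train: int = 0
    regularized: bool = False
    feature_abbreviations: tuple[str, ...] | None = None
    log_det_cov: float = field(init=False)
    _cho: tuple = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError(
                f"covariance shape {self.cov.shape} does not match "
                f"mean length {self.mean.size}"
            )
        if not np.allclose(self.cov, self.cov.T, rtol=1e-10, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")
        if not 0.0 < self.prior < 1.0:
            raise ValueError(f"prior must lie in (0, 1), got {self.prior}")
        try:
            self._cho = cho_factor(self.cov, lower=True)
        except LinAlgError as exc:
            raise ValueError(
                f"covariance for class {self.class_label!r} is not positive "
                "definite"
            ) from exc
        self.log_det_cov = 2.0 * float(np.sum(np.log(np.diag(self._cho[0]))))
        if not np.isfinite(self.log_det_cov):
            raise ValueError("ln|S| is not finite")

    @property
    def d(self) -> int:
        """Feature-space dimensionality."""
        return self.mean.size

    def squared_mahalanobis(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.d,):
            raise ValueError(f"expected vector of length {self.d}, got {x.shape}")
        diff = x - self.mean
        return float(diff @ cho_solve(self._cho, diff))

    def to_dict(self) -> dict:
        """JSON-serialisable representation (for `fit`/`classify` round trips)."""
        return {
            "class_label": self.class_label,
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "prior": self.prior,
            "n_train": self.n_train,
            "regularized": self.regularized,
            "feature_abbreviations": (
                list(self.feature_abbreviations)
                if self.feature_abbreviations is not None
                else None
            ),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ClassModel":
        abbrevs = payload.get("feature_abbreviations")
        return cls(
            class_label=payload["class_label"],
            mean=np.asarray(payload["mean"], dtype=float),
            cov=np.asarray(payload["cov"], dtype=float),
            prior=float(payload["prior"]),
            n_train=int(payload.get("n_train", 0)),
            regularized=bool(payload.get("regularized", False)),
            feature_abbreviations=tuple(abbrevs) if abbrevs else None,
        )


@dataclass
class DiscriminantScores:
    """Per-class δ and Mahalanobis r for one MUPT, plus the winning class."""

    class_labels: tuple[str, ...]
    log_discriminants: dict[str, float]
    mahalanobis_distances: dict[str, float]
    argmax_class: str
    tied: bool = False


def _is_positive_definite(matrix: np.ndarray) -> bool:
    try:
        cho_factor(matrix, lower=True)
    except LinAlgError:
        return False
    return bool(np.all(np.isfinite(matrix)))


def fit_class_model(
    records: Sequence[MUPTRecord] | np.ndarray,
    prior: float = 0.5,
    class_label: str | None = None,
) -> ClassModel:
    """Estimate a Gaussian class model from the training MUPTs of one class.

    The mean is the per-feature arithmetic mean; the covariance is the
    sample covariance (divisor n−1) about those means.  If the sample
    covariance is not positive definite (fewer than d+1 records, or
    degenerate data), a scale-aware ridge ε·(tr S / d)·I with ε = 1e−6
    (growing tenfold until positive definite) is added and a warning is
    logged; identical records yield εI.

    Parameters
    ----------
    records
        MUPTRecords of a single class, or a plain (n, d) matrix (then
        ``class_label`` must be given).
    prior
        Class prior P(ω), stored as given; defaults to the uninformative 0.5.
    """
    if isinstance(records, np.ndarray) or (
        len(records) > 0 and not isinstance(records[0], MUPTRecord)
    ):
        X = np.atleast_2d(np.asarray(records, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(records).ndim == 1:
            X = X.T  # a 1-D list of scalars is n observations of d=1
        if class_label is None:
            raise ValueError("class_label is required when fitting from a matrix")
        label = class_label
    else:
        records = list(records)
        if not records:
            raise ModelEstimationError("no records to fit")
        labels = {rec.true_class for rec in records}
        if len(labels) > 1:
            raise ValueError(f"records span multiple classes: {sorted(labels)}")
        label = class_label or records[0].true_class
        X = np.vstack([rec.features for rec in records])

    n, d = X.shape
    if n < 2:
        raise ModelEstimationError(
            f"need at least 2 records to estimate a covariance, got {n}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("training records contain non-finite values")

    mean = X.mean(axis=0)
    cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))

    regularized = False
    if not _is_positive_definite(cov):
        scale = float(np.trace(cov)) / d
        if scale <= 0.0:
            scale = 1.0
        eps = RIDGE_EPS
        while eps < 1e3:
            candidate = cov + eps * scale * np.eye(d)
            if _is_positive_definite(candidate):
                cov = candidate
                break
            eps *= 10.0
        else:  # pragma: no cover - unreachable for finite input
            raise ModelEstimationError("covariance could not be regularised")
        regularized = True
        logger.warning(
            "covariance for class %r (n=%d, d=%d) was singular; "
            "added ridge %.3g·I", label, n, d, eps * scale,
        )

    return ClassModel(
        class_label=label,
        mean=mean,
        cov=cov,
        prior=prior,
        n_train=n,
        regularized=regularized,
    )


def log_discriminant(model: ClassModel, x: Sequence[float] | np.ndarray) -> float:
    """δ(x) = −½ r² − ½ ln|S| + ln P(ω); the Gaussian log-density discriminant."""
    q = model.squared_mahalanobis(np.asarray(x, dtype=float))
    return -0.5 * q - 0.5 * model.log_det_cov + float(np.log(model.prior))


def mahalanobis(model: ClassModel, x: Sequence[float] | np.ndarray) -> float:
    """Distance of x from the class mean in units of standard deviation."""
    return float(np.sqrt(model.squared_mahalanobis(np.asarray(x, dtype=float))))


def classify_mupt(
    models: Sequence[ClassModel],
    x: Sequence[float] | np.ndarray,
) -> DiscriminantScores:
    """Score one MUPT against every class model and pick the maximal δ.

    An exact tie in δ is flagged and broken toward the first-listed model,
    with a logged warning (ties have measure zero for continuous features
    but must be deterministic when they occur).
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least two class models")
    dims = {m.d for m in models}
    if len(dims) > 1:
        raise ValueError(f"models disagree on dimensionality: {sorted(dims)}")
    labels = tuple(m.class_label for m in models)
    if len(set(labels)) != len(labels):
        raise ValueError("class labels must be distinct")

    x = np.asarray(x, dtype=float)
    deltas: dict[str, float] = {}
    dists: dict[str, float] = {}
    for model in models:
        q = model.squared_mahalanobis(x)
        deltas[model.class_label] = (
            -0.5 * q - 0.5 * model.log_det_cov + float(np.log(model.prior))
        )
        dists[model.class_label] = float(np.sqrt(q))

    best = max(deltas.values())
    winners = [lab for lab in labels if deltas[lab] == best]
    tied = len(winners) > 1
    if tied:
        logger.warning(
            "exact discriminant tie between %s; assigning first-listed %r",
            winners, winners[0],
        )
    return DiscriminantScores(
        class_labels=labels,
        log_discriminants=deltas,
        mahalanobis_distances=dists,
        argmax_class=winners[0],
        tied=tied,
    )
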
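"""Evaluation statistics for muscle characterization experiments.

Covers the full reporting surface of the characterization study design:

* 2×2 confusion matrices with per-class accuracies, overall accuracy and
  the "Performance" metric — the product of the per-class accuracies,
  which weights both classes equally under imbalance and is bounded in
  [0, 1] (monotone in each per-class accuracy, though non-linear).
  Treating NSAP as the positive outcome, the NSAP-class accuracy is the
  sensitivity and the Normative-class accuracy the specificity.
* McNemar's paired test over two classifiers' correctness on the same
  studies, built from the discordant pairs α (first wrong, second right;
  "improved") and β (first right, second wrong; "degraded"), with the
  continuity-corrected χ² = (|α−β|−1)²/(α+β) on 1 d.f., the α/β odds
  ratio and a Woolf log-interval CI.
* Feature-stability statistics across cross-validation folds: for each
  feature and class, the spread of the fold-wise means against the mean
  within-fold SD (stability ratio ψ), and a between-class separation
  t-statistic weighted by the number of folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import CLASS_LABELS, NORMATIVE, NSAP
from .nddf import ClassModel

__all__ = [
    "ConfusionMatrix",
    "McNemarResult",
    "PairCounts",
    "UndefinedTestError",
    "MismatchedStudySetError",
    "confusion",
    "discordant_pairs",
    "mcnemar",
    "feature_stability",
    "separation_t",
    "stability_ratio",
    "round_half_up",
]


class UndefinedTestError(ValueError):
    """McNemar's test is undefined when there are no discordant pairs."""


class MismatchedStudySetError(ValueError):
    """Two prediction sets do not cover the same studies."""


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero (display convention for metrics)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """2×2 confusion counts plus the derived accuracy metrics.

    ``counts[i][j]`` is the number of items with true class ``labels[i]``
    assigned class ``labels[j]``.  All metrics are computed from the
    unrounded count ratios; rounding is applied only for display.
    """

    counts: np.ndarray
    labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}×{k}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=1) == 0):
            raise ValueError("every true class must have at least one item")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def per_class_accuracy(self) -> dict[str, float]:
        diag = np.diag(self.counts)
        return {
            lab: float(diag[i] / self.row_totals[i])
            for i, lab in enumerate(self.labels)
        }

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.n)

    @property
    def performance(self) -> float:
        """Product of unrounded per-class accuracies."""
        return float(np.prod(list(self.per_class_accuracy.values())))

    @property
    def sensitivity(self) -> float:
        """NSAP-class accuracy (NSAP = positive test outcome)."""
        return self.per_class_accuracy[NSAP]

    @property
    def specificity(self) -> float:
        """Normative-class accuracy (Normative = negative test outcome)."""
        return self.per_class_accuracy[NORMATIVE]

    def to_text(self, title: str = "", unit: str = "items") -> str:
        acc = self.per_class_accuracy
        lines = []
        if title:
            lines.append(title)
        header = f"{'True label':<12}" + "".join(
            f"{lab:>12}" for lab in self.labels
        ) + f"{'Totals':>10}{'Accuracy':>10}"
        lines.append(header)
        for i, lab in enumerate(self.labels):
            row = f"{lab:<12}" + "".join(
                f"{int(c):>12}" for c in self.counts[i]
            )
            row += f"{int(self.row_totals[i]):>10}{round_half_up(acc[lab]):>10.3f}"
            lines.append(row)
        col_totals = self.counts.sum(axis=0)
        lines.append(
            f"{'Totals':<12}" + "".join(f"{int(c):>12}" for c in col_totals)
            + f"{'':>10}{round_half_up(self.performance):>10.3f}"
        )
        lines.append(f"({self.n} {unit}; Performance = product of per-class accuracies)")
        return "\n".join(lines)


def confusion(
    predictions: Iterable[tuple[str, str]],
    labels: tuple[str, ...] = CLASS_LABELS,
) -> ConfusionMatrix:
    """Tally (true_class, assigned_class) pairs into a ConfusionMatrix."""
    predictions = list(predictions)
    if not predictions:
        raise ValueError("no predictions to tally")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for true, assigned in predictions:
        try:
            counts[index[true], index[assigned]] += 1
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in {labels}") from None
    return ConfusionMatrix(counts=counts, labels=labels)


class PairCounts(NamedTuple):
    """Paired correctness tallies of two classifiers on the same studies."""

    both_correct: int
    both_wrong: int
    improved: int   # A wrong, B correct (discordant pair α)
    degraded: int   # A correct, B wrong (discordant pair β)


def discordant_pairs(
    result_a: Iterable[tuple[str, str, str]],
    result_b: Iterable[tuple[str, str, str]],
) -> PairCounts:
    """Tally paired correctness of two prediction sets keyed by study id.

    Inputs are (study_id, true_class, assigned_class) triples; the two
    sets must cover identical study ids (order-independent).
    """
    def correctness(result) -> dict[str, bool]:
        table = {}
        for sid, true, assigned in result:
            if sid in table:
                raise ValueError(f"duplicate study id {sid!r} in predictions")
            table[sid] = true == assigned
        return table

    a = correctness(result_a)
    b = correctness(result_b)
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))
        only_b = sorted(set(b) - set(a))
        raise MismatchedStudySetError(
            f"prediction sets differ: only in A {only_a}, only in B {only_b}"
        )
    counts = PairCounts(
        both_correct=sum(1 for s in a if a[s] and b[s]),
        both_wrong=sum(1 for s in a if not a[s] and not b[s]),
        improved=sum(1 for s in a if not a[s] and b[s]),
        degraded=sum(1 for s in a if a[s] and not b[s]),
    )
    return counts


@dataclass
class McNemarResult:
    """Continuity-corrected McNemar test over discordant pairs α, β."""

    improved: int
    degraded: int
    chi2: float
    p_two_tailed: float
    odds_ratio: float
    ci95: tuple[float, float] | None

    def to_text(self) -> str:
        or_txt = (
            "inf" if np.isinf(self.odds_ratio) else f"{self.odds_ratio:.3f}"
        )
        ci_txt = (
            f"{self.ci95[0]:.3g} ... {self.ci95[1]:.3g}" if self.ci95 else "undefined"
        )
        return (
            f"improved={self.improved} degraded={self.degraded} "
            f"chi2={self.chi2:.3f} p={self.p_two_tailed:.2f} "
            f"OR={or_txt} CI95=[{ci_txt}]"
        )


def mcnemar(improved: int, degraded: int) -> McNemarResult:
    """McNemar χ² on 1 d.f. from the two discordant-pair counts.

    χ² = (|α−β|−1)² / (α+β) with Edwards' continuity correction (for
    α = β this yields 1/(α+β)); the two-tailed p is the upper tail of
    χ²₁.  The odds ratio is α/β (infinite when β = 0) with a Woolf
    log-interval 95% CI, defined only when both counts are positive.
    """
    a, b = int(improved), int(degraded)
    if a < 0 or b < 0:
        raise ValueError("discordant-pair counts must be non-negative")
    if a + b == 0:
        raise UndefinedTestError(
            "McNemar's test is undefined with no discordant pairs"
        )
    chi2 = (abs(a - b) - 1) ** 2 / (a + b)
    p = float(stats.chi2.sf(chi2, df=1))
    if b == 0:
        odds, ci = float("inf"), None
    else:
        odds = a / b
        if a == 0:
            ci = None
        else:
            half = 1.96 * np.sqrt(1.0 / a + 1.0 / b)
            ci = (
                float(np.exp(np.log(odds) - half)),
                float(np.exp(np.log(odds) + half)),
            )
    return McNemarResult(
        improved=a, degraded=b, chi2=float(chi2), p_two_tailed=p,
        odds_ratio=float(odds), ci95=ci,
    )


def separation_t(
    mean_a: float | np.ndarray,
    mean_b: float | np.ndarray,
    sd_a: float | np.ndarray,
    sd_b: float | np.ndarray,
    df: int,
) -> float | np.ndarray:
    """Between-class separation: |Δμ| / sqrt((σ_a² + σ_b²)/df).

    The mean difference is normalised by the classes' mean within-fold
    SDs, weighted by the d.f. introduced by the cross-validation folds
    (df = number of folds).  Reported as a magnitude.
    """
    t = np.abs(np.asarray(mean_a) - np.asarray(mean_b)) / np.sqrt(
        (np.asarray(sd_a) ** 2 + np.asarray(sd_b) ** 2) / df
    )
    return float(t) if np.ndim(t) == 0 else t


def stability_ratio(
    mean_within_sd: float | np.ndarray,
    sd_of_fold_means: float | np.ndarray,
) -> float | np.ndarray:
    """ψ: mean within-fold SD over the SD of fold-wise means.

    Large ψ means the fold-to-fold wobble of the estimated mean is small
    relative to the feature's own spread, i.e. the location estimate is
    stable.  Infinite (with a warning) when the fold means are identical.
    """
    sd_of_fold_means = np.asarray(sd_of_fold_means, dtype=float)
    if np.any(sd_of_fold_means == 0):
        warnings.warn(
            "fold means are identical for some feature; ψ is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        psi = np.asarray(mean_within_sd, dtype=float) / sd_of_fold_means
    return float(psi) if np.ndim(psi) == 0 else psi


def feature_stability(
    fold_models: Sequence[Mapping[str, ClassModel]],
    feature_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-feature stability and separation statistics across CV folds.

    For each class: the mean of the fold-wise feature means μ(μ), their SD
    σ(μ) (divisor n−1), the mean of the fold-wise per-feature SDs μ(σ)
    (square roots of the covariance diagonal), and ψ = μ(σ)/σ(μ).  The
    ``t`` column is :func:`separation_t` between the two classes with
    σ = μ(σ) and df = number of folds.
    """
    if len(fold_models) < 2:
        raise ValueError("need at least 2 folds for stability statistics")
    labels = CLASS_LABELS
    d = next(iter(fold_models[0].values())).d
    for fold in fold_models:
        for lab in labels:
            if lab not in fold:
                raise ValueError(f"fold is missing a model for class {lab!r}")
            if fold[lab].d != d:
                raise ValueError("fold models disagree on feature count")

    if feature_names is None:
        abbrevs = fold_models[0][labels[0]].feature_abbreviations
        feature_names = list(abbrevs) if abbrevs else [f"f{i}" for i in range(d)]
    if len(feature_names) != d:
        raise ValueError(f"expected {d} feature names, got {len(feature_names)}")

    n_folds = len(fold_models)
    data: dict[str, np.ndarray] = {}
    per_class_sigma: dict[str, np.ndarray] = {}
    per_class_mu: dict[str, np.ndarray] = {}
    for lab in labels:
        fold_means = np.vstack([fold[lab].mean for fold in fold_models])
        fold_sds = np.vstack(
            [np.sqrt(np.diag(fold[lab].cov)) for fold in fold_models]
        )
        mu_mu = fold_means.mean(axis=0)
        sd_mu = fold_means.std(axis=0, ddof=1)
        mu_sd = fold_sds.mean(axis=0)
        per_class_mu[lab] = mu_mu
        per_class_sigma[lab] = mu_sd
        data[f"{lab}_mean"] = mu_mu
        data[f"{lab}_sd_of_fold_means"] = sd_mu
        data[f"{lab}_mean_fold_sd"] = mu_sd
        data[f"{lab}_psi"] = stability_ratio(mu_sd, sd_mu)

    data["t"] = separation_t(
        per_class_mu[labels[0]],
        per_class_mu[labels[1]],
        per_class_sigma[labels[0]],
        per_class_sigma[labels[1]],
        df=n_folds,
    )
    return pd.DataFrame(data, index=list(feature_names))
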
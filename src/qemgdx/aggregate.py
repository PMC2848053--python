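"""Muscle-level aggregation of per-MUPT discriminant scores.

A condition with variable motor-unit involvement leaves both
normative-looking and involved MUPTs in the same muscle, so no single
MUPT characterisation is decisive.  Four schemes turn the set of per-MUPT
scores from one muscle study into a muscle characterization:

``independent``
    No aggregation: each MUPT keeps its own argmax label (the baseline).
``vote``
    Majority vote over per-MUPT argmax labels; exact ties are broken
    uniformly at random from a caller-provided seeded generator.
``bayes``
    Sum of per-MUPT log-discriminants per class, ln Δ_k = Σ_i δ_k(x_i) —
    the log of the product of prior-weighted class densities across the
    muscle's MUPTs, with the class-independent normalisation dropped;
    argmax of ln Δ_k wins.  This weighs each MUPT by how strongly it
    favours a class, unlike the vote.
``mean_distance``
    Per class, the mean Mahalanobis distance of the muscle's MUPTs from
    the class mean; the closest (argmin) class wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nddf import DiscriminantScores

__all__ = [
    "SCHEME_INDEPENDENT",
    "SCHEME_VOTE",
    "SCHEME_BAYES",
    "SCHEME_MEAN_DISTANCE",
    "SCHEMES",
    "MuscleCharacterization",
    "vote_aggregate",
    "bayes_aggregate",
    "mean_distance_aggregate",
    "independent_characterize",
]

logger = logging.getLogger(__name__)

SCHEME_INDEPENDENT = "independent"
SCHEME_VOTE = "vote"
SCHEME_BAYES = "bayes"
SCHEME_MEAN_DISTANCE = "mean_distance"
SCHEMES = (SCHEME_INDEPENDENT, SCHEME_VOTE, SCHEME_BAYES, SCHEME_MEAN_DISTANCE)


@dataclass
class MuscleCharacterization:
    """One muscle study's aggregate class assignment under one scheme.

    ``scores`` holds the per-class aggregate the scheme optimised: vote
    counts, summed log-discriminants ln Δ_k, or mean Mahalanobis distance.
    """

    study_id: str
    scheme: str
    assigned_class: str
    scores: dict[str, float]
    tie_broken: bool = False


def _check_scores(scores: Sequence[DiscriminantScores]) -> tuple[str, ...]:
    scores = list(scores)
    if not scores:
        raise ValueError("cannot aggregate an empty list of MUPT scores")
    labels = scores[0].class_labels
    for s in scores:
        if s.class_labels != labels:
            raise ValueError("MUPT scores disagree on class labels")
    return labels


def vote_aggregate(
    scores: Sequence[DiscriminantScores],
    rng: np.random.Generator,
    study_id: str = "",
) -> MuscleCharacterization:
    """Majority vote over per-MUPT argmax labels.

    Each MUPT contributes one unweighted vote to its argmax class; the
    margin of its discriminant plays no role.  An exact tie in counts is
    broken uniformly at random from ``rng`` (flagged via ``tie_broken``).
    """
    labels = _check_scores(scores)
    counts = {lab: 0.0 for lab in labels}
    for s in scores:
        counts[s.argmax_class] += 1.0
    top = max(counts.values())
    winners = [lab for lab in labels if counts[lab] == top]
    if len(winners) > 1:
        assigned = winners[int(rng.integers(len(winners)))]
        tie = True
    else:
        assigned, tie = winners[0], False
    return MuscleCharacterization(study_id, SCHEME_VOTE, assigned, counts, tie)


def bayes_aggregate(
    scores: Sequence[DiscriminantScores],
    study_id: str = "",
) -> MuscleCharacterization:
    """Joint-probability aggregation: per class, sum the log-discriminants.

    ln Δ_k = Σ_i δ_k(x_i) is the log of the product of prior-weighted class
    densities over the muscle's MUPTs (normalisation dropped, as it is
    common to both classes); the class with maximal ln Δ_k is assigned.
    With a single MUPT this reduces to the per-MUPT decision.  Exact ties
    (not expected for continuous features) break deterministically to the
    first-listed class and are flagged.
    """
    labels = _check_scores(scores)
    totals = {
        lab: float(sum(s.log_discriminants[lab] for s in scores)) for lab in labels
    }
    if not all(np.isfinite(v) for v in totals.values()):
        raise ValueError(f"non-finite aggregate discriminant for study {study_id!r}")
    top = max(totals.values())
    winners = [lab for lab in labels if totals[lab] == top]
    tie = len(winners) > 1
    if tie:
        logger.warning("bayes aggregate tie for study %r; assigning %r",
                       study_id, winners[0])
    return MuscleCharacterization(study_id, SCHEME_BAYES, winners[0], totals, tie)


def mean_distance_aggregate(
    scores: Sequence[DiscriminantScores],
    study_id: str = "",
) -> MuscleCharacterization:
    """Assign the class with the smallest mean Mahalanobis distance.

    Averages r_k over the muscle's MUPTs per class and picks the argmin
    ("closest" class).  Because r ignores both the prior and ln|S|, this
    can legitimately disagree with :func:`bayes_aggregate` when class
    covariances differ.  Exact ties break to the first-listed class.
    """
    labels = _check_scores(scores)
    means = {
        lab: float(np.mean([s.mahalanobis_distances[lab] for s in scores]))
        for lab in labels
    }
    best = min(means.values())
    winners = [lab for lab in labels if means[lab] == best]
    tie = len(winners) > 1
    if tie:
        logger.warning("mean-distance tie for study %r; assigning %r",
                       study_id, winners[0])
    return MuscleCharacterization(
        study_id, SCHEME_MEAN_DISTANCE, winners[0], means, tie
    )


def independent_characterize(
    scores: Sequence[DiscriminantScores],
) -> list[str]:
    """Per-MUPT argmax labels in input order (the unaggregated baseline)."""
    scores = list(scores)
    if not scores:
        raise ValueError("no MUPT scores given")
    return [s.argmax_class for s in scores]
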
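"""Grouped round-robin cross-validation at muscle-study granularity.

A muscle study's MUPTs are statistically dependent (same subject, same
muscle, same session), so splitting them across folds would leak
information from test to train.  Studies are therefore dealt whole:
walking the NSAP list and the normative list separately and assigning
each subsequent study to the next pool in round-robin fashion, which
keeps both classes represented in every pool despite the class imbalance.
Each pool serves exactly once as the test set, with the remaining pools
pooled for training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import aggregate as agg
from .features import CLASS_LABELS, StudyCollection
from .nddf import ClassModel, DiscriminantScores, classify_mupt, fit_class_model

__all__ = [
    "PoolAssignment",
    "ExperimentResult",
    "FoldError",
    "build_pools",
    "run_experiment",
]


class FoldError(ValueError):
    """A fold cannot be trained or tested as constructed."""


@dataclass
class PoolAssignment:
    """Mapping of every study id to exactly one cross-validation pool."""

    n_pools: int
    assignment: dict[str, int]

    def pool_members(self, pool: int) -> list[str]:
        return [sid for sid, p in self.assignment.items() if p == pool]

    def pools(self) -> list[list[str]]:
        return [self.pool_members(p) for p in range(self.n_pools)]


@dataclass
class ExperimentResult:
    """Predictions, fold models and pool structure from one experiment.

    ``predictions`` maps each aggregation scheme to a list of
    (study_id, true_class, assigned_class) triples covering every study
    exactly once; ``mupt_predictions`` holds the per-MUPT baseline triples.
    Fold-wise class models are retained to compute feature-stability
    statistics afterwards.
    """

    predictions: dict[str, list[tuple[str, str, str]]]
    mupt_predictions: list[tuple[str, str, str]]
    fold_models: list[dict[str, ClassModel]]
    pool_assignment: PoolAssignment
    tie_broken_studies: dict[str, list[str]] = field(default_factory=dict)

    def pairs(self, scheme: str) -> list[tuple[str, str]]:
        """(true, assigned) pairs for a scheme; ``independent`` = per MUPT."""
        if scheme == agg.SCHEME_INDEPENDENT:
            return [(t, a) for _, t, a in self.mupt_predictions]
        return [(t, a) for _, t, a in self.predictions[scheme]]

    def to_dict(self) -> dict:
        return {
            "predictions": {
                scheme: [list(p) for p in preds]
                for scheme, preds in self.predictions.items()
            },
            "mupt_predictions": [list(p) for p in self.mupt_predictions],
            "fold_models": [
                {lab: m.to_dict() for lab, m in fold.items()}
                for fold in self.fold_models
            ],
            "pool_assignment": {
                "n_pools": self.pool_assignment.n_pools,
                "assignment": dict(self.pool_assignment.assignment),
            },
            "tie_broken_studies": dict(self.tie_broken_studies),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ExperimentResult":
        return cls(
            predictions={
                scheme: [tuple(p) for p in preds]
                for scheme, preds in payload["predictions"].items()
            },
            mupt_predictions=[tuple(p) for p in payload["mupt_predictions"]],
            fold_models=[
                {lab: ClassModel.from_dict(m) for lab, m in fold.items()}
                for fold in payload["fold_models"]
            ],
            pool_assignment=PoolAssignment(
                n_pools=int(payload["pool_assignment"]["n_pools"]),
                assignment={
                    str(k): int(v)
                    for k, v in payload["pool_assignment"]["assignment"].items()
                },
            ),
            tie_broken_studies={
                k: list(v)
                for k, v in payload.get("tie_broken_studies", {}).items()
            },
        )


def build_pools(
    collection: StudyCollection,
    n_pools: int = 10,
    order: str = "input",
    seed: int | None = None,
) -> PoolAssignment:
    """Deal muscle studies into pools, round-robin within each class.

    With ``order="input"`` studies are walked in collection order (the
    default; deterministic); ``order="seeded-shuffle"`` shuffles each
    class list first with ``seed``, for sensitivity analyses.  Study i of
    a class lands in pool i mod n_pools, so class representation per pool
    is as even as the counts allow and no study's MUPTs are ever split.
    """
    if n_pools < 2:
        raise ValueError(f"need at least 2 pools, got {n_pools}")
    if collection.n_studies < n_pools:
        raise ValueError(
            f"{collection.n_studies} studies cannot fill {n_pools} pools"
        )
    largest = max(
        len(collection.studies_of(lab)) for lab in CLASS_LABELS
    )
    if n_pools > largest:
        raise ValueError(
            f"n_pools={n_pools} exceeds the study count of the larger class "
            f"({largest})"
        )
    if order not in ("input", "seeded-shuffle"):
        raise ValueError(f"unknown order {order!r}")

    rng = np.random.default_rng(seed) if order == "seeded-shuffle" else None
    assignment: dict[str, int] = {}
    for label in CLASS_LABELS:
        ids = [s.study_id for s in collection.studies_of(label)]
        if rng is not None:
            rng.shuffle(ids)
        for i, sid in enumerate(ids):
            assignment[sid] = i % n_pools
    return PoolAssignment(n_pools=n_pools, assignment=assignment)


def run_experiment(
    collection: StudyCollection,
    n_pools: int = 10,
    seed: int = 0,
    priors: Sequence[float] = (0.5, 0.5),
    order: str = "input",
) -> ExperimentResult:
    """Run the full cross-validated, four-scheme characterization experiment.

    For each fold: fit one Gaussian model per class on all MUPTs of the
    training pools (priors fixed at ``priors``, aligned with
    ``CLASS_LABELS`` — by default uninformative 0.5/0.5, never re-estimated
    from fold frequencies), score every test-pool MUPT, then apply the
    independent baseline and the vote / bayes / mean-distance aggregations
    per test study.  ``seed`` drives vote tie-breaking (and the optional
    shuffle order).
    """
    priors = tuple(float(p) for p in priors)
    if len(priors) != len(CLASS_LABELS):
        raise ValueError(f"need {len(CLASS_LABELS)} priors, got {len(priors)}")
    if abs(sum(priors) - 1.0) > 1e-9:
        raise ValueError(f"priors must sum to 1, got {priors}")
    for label in CLASS_LABELS:
        if not collection.studies_of(label):
            raise ValueError(f"collection has no studies of class {label!r}")

    pools = build_pools(collection, n_pools=n_pools, order=order, seed=seed)
    rng = np.random.default_rng(seed)
    by_id = {s.study_id: s for s in collection.studies}

    predictions: dict[str, list[tuple[str, str, str]]] = {
        agg.SCHEME_VOTE: [],
        agg.SCHEME_BAYES: [],
        agg.SCHEME_MEAN_DISTANCE: [],
    }
    mupt_predictions: list[tuple[str, str, str]] = []
    fold_models: list[dict[str, ClassModel]] = []
    tie_broken: dict[str, list[str]] = {s: [] for s in predictions}

    for fold in range(n_pools):
        test_ids = set(pools.pool_members(fold))
        train_studies = [s for s in collection.studies if s.study_id not in test_ids]

        models: list[ClassModel] = []
        for label, prior in zip(CLASS_LABELS, priors):
            train = [s for s in train_studies if s.true_class == label]
            if not train:
                raise FoldError(
                    f"training data for fold {fold} contains no {label} studies"
                )
            X = np.vstack([s.feature_matrix for s in train])
            model = fit_class_model(X, prior=prior, class_label=label)
            model.feature_abbreviations = tuple(
                f.abbreviation for f in collection.feature_set
            )
            models.append(model)
        fold_models.append({m.class_label: m for m in models})

        # collection order keeps the experiment deterministic under a seed
        for study in collection.studies:
            if study.study_id not in test_ids:
                continue
            scores: list[DiscriminantScores] = [
                classify_mupt(models, x) for x in study.feature_matrix
            ]
            for label in agg.independent_characterize(scores):
                mupt_predictions.append((study.study_id, study.true_class, label))
            for scheme, char in (
                (agg.SCHEME_VOTE, agg.vote_aggregate(scores, rng, study.study_id)),
                (agg.SCHEME_BAYES, agg.bayes_aggregate(scores, study.study_id)),
                (
                    agg.SCHEME_MEAN_DISTANCE,
                    agg.mean_distance_aggregate(scores, study.study_id),
                ),
            ):
                predictions[scheme].append(
                    (study.study_id, study.true_class, char.assigned_class)
                )
                if char.tie_broken:
                    tie_broken[scheme].append(study.study_id)

    for scheme, preds in predictions.items():
        covered = {sid for sid, _, _ in preds}
        if covered != set(by_id):
            raise FoldError(  # pragma: no cover - structural self-check
                f"scheme {scheme!r} predictions do not cover every study"
            )

    return ExperimentResult(
        predictions=predictions,
        mupt_predictions=mupt_predictions,
        fold_models=fold_models,
        pool_assignment=pools,
        tie_broken_studies=tie_broken,
    )
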
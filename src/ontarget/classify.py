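"""Nearest-neighbor target-group classifiers with majority voting.

Two predictors share one decision procedure:

* **Ontology backend** — for a query drug, find every training drug whose
  mean term-graph distance Q to the query attains the exact minimum over the
  training set (ties are real: Q is compared as an exact fraction).
* **Interaction backend** — find every training drug whose chemical-chemical
  combined interaction score I with the query attains the maximum, provided
  that maximum is positive (a score of 0 encodes non-interaction and carries
  no evidence).

The target groups of the optimal-score neighbors are then put to a vote: the
group with the most votes is the prediction, and a tie among modes is broken
uniformly at random with a caller-supplied seed.  When no training drug
yields a usable score (every Q undefined, or every I zero) the classifier
abstains — an explicit *no prediction*, distinct from an error.

Both classifiers follow the scikit-learn estimator protocol (``fit`` /
``predict`` / ``get_params``), so they compose with ``sklearn.clone`` and
model-selection utilities; the module-level functions are thin wrappers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .data import DrugRecord, InteractionTable, TrainingSet
from .ontology import OntologyGraph
from .similarity import compound_similarity

__all__ = [
    "NeighborSet",
    "Prediction",
    "OntologyNeighborClassifier",
    "InteractionNeighborClassifier",
    "nearest_by_ontology",
    "nearest_by_interaction",
    "vote",
    "predict",
]


@dataclass(frozen=True)
class NeighborSet:
    """All training drugs sharing the optimal score against one query.

    ``criterion`` records which rule selected them: ``"min_Q"`` (smallest
    mean ontology distance) or ``"max_I"`` (largest interaction score).
    Every member's score is exactly equal to every other's.
    """

    members: tuple[tuple[DrugRecord, object], ...]
    criterion: str

    def __post_init__(self):
        if not self.members:
            raise ValueError("a NeighborSet must be non-empty")
        scores = {score for _, score in self.members}
        if len(scores) != 1:
            raise ValueError(f"neighbor scores are not all equal: {scores}")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def score(self):
        """The shared optimal score."""
        return self.members[0][1]

    @property
    def records(self) -> list[DrugRecord]:
        return [rec for rec, _ in self.members]


@dataclass(frozen=True)
class Prediction:
    """Outcome of one query: winning group, vote tally, and provenance.

    ``predicted_group`` is ``None`` for a no-prediction outcome (abstention).
    ``tie_broken`` is True when the winner was chosen at random among
    equally voted groups.
    """

    drug_id: str
    predicted_group: Optional[str]
    votes: dict[str, int] = field(default_factory=dict)
    neighbors: Optional[NeighborSet] = None
    tie_broken: bool = False

    @property
    def abstained(self) -> bool:
        return self.predicted_group is None

    def to_dict(self) -> dict:
        """JSON-serializable summary (scores rendered as strings)."""
        return {
            "drug_id": self.drug_id,
            "predicted_group": self.predicted_group,
            "votes": dict(self.votes),
            "neighbors": [
                {"drug_id": rec.drug_id, "group": rec.group, "score": str(score)}
                for rec, score in (self.neighbors.members if self.neighbors else ())
            ],
            "tie_broken": self.tie_broken,
        }


# ---------------------------------------------------------------------------
# neighbor searches


def nearest_by_ontology(
    g: OntologyGraph, query_terms: Iterable[str], train: TrainingSet
) -> Optional[NeighborSet]:
    """Training drugs at the exact minimum mean ontology distance Q.

    Candidates with undefined Q (some term pair unreachable) are skipped;
    returns ``None`` when every training drug's Q is undefined.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    best: Optional[Fraction] = None
    members: list[tuple[DrugRecord, Fraction]] = []
    for rec in train:
        q = compound_similarity(g, query_terms, rec.terms)
        if q is None:
            continue
        if best is None or q < best:
            best = q
            members = [(rec, q)]
        elif q == best:
            members.append((rec, q))
    if best is None:
        return None
    return NeighborSet(tuple(members), criterion="min_Q")


def nearest_by_interaction(
    table: InteractionTable, query_id: str, train: TrainingSet
) -> Optional[NeighborSet]:
    """Training drugs at the maximum interaction score I, if that maximum > 0.

    Returns ``None`` (no prediction) when the query interacts with no
    training drug: I = 0 means non-interaction, not a zero-score tie.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    best = 0.0
    members: list[tuple[DrugRecord, float]] = []
    for rec in train:
        score = table.score(query_id, rec.drug_id)
        if score <= 0:
            continue
        if score > best:
            best = score
            members = [(rec, score)]
        elif score == best:
            members.append((rec, score))
    if not members:
        return None
    return NeighborSet(tuple(members), criterion="max_I")


# ---------------------------------------------------------------------------
# voting


def vote(neighbors: NeighborSet, seed=None, drug_id: str = "") -> Prediction:
    """Majority vote over the neighbor groups, random tie-break.

    Each neighbor casts one vote for its target group; the group with the
    most votes wins.  If several groups share the top count, one is chosen
    uniformly at random by a generator seeded with ``seed`` (anything
    ``numpy.random.default_rng`` accepts), and ``tie_broken`` is set.
    """
    tally = Counter(rec.group for rec in neighbors.records)
    top = max(tally.values())
    modes = sorted(g for g, n in tally.items() if n == top)
    if len(modes) == 1:
        winner, tie_broken = modes[0], False
    else:
        rng = np.random.default_rng(seed)
        winner = modes[int(rng.integers(len(modes)))]
        tie_broken = True
    return Prediction(
        drug_id=drug_id,
        predicted_group=winner,
        votes=dict(tally),
        neighbors=neighbors,
        tie_broken=tie_broken,
    )


# ---------------------------------------------------------------------------
# estimators


class _NeighborVoteClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery for both neighbor-vote backends."""

    random_state: Optional[int]

    def fit(self, X, y):
        X = list(X)
        y = list(y)
        if len(X) != len(y):
            raise ValueError(f"X and y lengths differ: {len(X)} vs {len(y)}")
        if len(X) == 0:
            raise ValueError("cannot fit on an empty training set")
        self._check_resources()
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        self._train_ids_ = None
        self._records_cache_ = None
        return self

    def fit_records(self, train: TrainingSet):
        """Fit from a :class:`TrainingSet` (features extracted per backend)."""
        self.fit([self.features_of(rec) for rec in train],
                 [rec.group for rec in train])
        self._train_ids_ = train.drug_ids
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted group per query; ``None`` marks an abstention."""
        details = self.predict_detail(X)
        return np.array([p.predicted_group for p in details], dtype=object)

    def predict_detail(
        self, X, drug_ids: Optional[Sequence[str]] = None
    ) -> list[Prediction]:
        """Full :class:`Prediction` per query (votes, neighbors, tie flag).

        Tie-break randomness for the i-th query comes from a generator
        seeded with ``(random_state, i)``, so each query is independently
        reproducible.
        """
        check_is_fitted(self, "X_")
        out: list[Prediction] = []
        for i, x in enumerate(X):
            qid = drug_ids[i] if drug_ids is not None else ""
            neighbors = self._neighbors(x)
            if neighbors is None:
                out.append(Prediction(drug_id=qid, predicted_group=None))
                continue
            seed = None if self.random_state is None else [self.random_state, i]
            out.append(vote(neighbors, seed=seed, drug_id=qid))
        return out

    def _training_records(self) -> TrainingSet:
        if getattr(self, "_records_cache_", None) is None:
            self._records_cache_ = TrainingSet(
                [self._record_of(i, x, g) for i, (x, g) in
                 enumerate(zip(self.X_, self.y_))]
            )
        return self._records_cache_

    # subclass hooks -------------------------------------------------------

    def _check_resources(self) -> None:
        raise NotImplementedError

    def _neighbors(self, x) -> Optional[NeighborSet]:
        raise NotImplementedError

    @staticmethod
    def features_of(record: DrugRecord):
        raise NotImplementedError

    def _record_of(self, i: int, x, group: str) -> DrugRecord:
        raise NotImplementedError


class OntologyNeighborClassifier(_NeighborVoteClassifier):
    """Minimum-mean-ontology-distance neighbor classifier.

    Parameters
    ----------
    graph
        The :class:`OntologyGraph` distances are computed on.
    random_state
        Master seed for tie-break randomness; ``None`` leaves ties
        nondeterministic.

    Samples ``X`` are collections of ontology term ids, one per drug.
    """

    def __init__(self, graph: Optional[OntologyGraph] = None,
                 random_state: Optional[int] = None):
        self.graph = graph
        self.random_state = random_state

    def _check_resources(self) -> None:
        if self.graph is None:
            raise ValueError("OntologyNeighborClassifier requires graph=")

    def _neighbors(self, x) -> Optional[NeighborSet]:
        return nearest_by_ontology(self.graph, x, self._training_records())

    @staticmethod
    def features_of(record: DrugRecord):
        return record.terms

    def _record_of(self, i: int, x, group: str) -> DrugRecord:
        ids = getattr(self, "_train_ids_", None)
        drug_id = ids[i] if ids is not None else f"train-{i}"
        return DrugRecord(drug_id, group, frozenset(x))


class InteractionNeighborClassifier(_NeighborVoteClassifier):
    """Maximum-interaction-score neighbor classifier.

    Parameters
    ----------
    interactions
        The :class:`InteractionTable` of combined scores.
    random_state
        Master seed for tie-break randomness.

    Samples ``X`` are drug id strings (the table is keyed by id).
    """

    def __init__(self, interactions: Optional[InteractionTable] = None,
                 random_state: Optional[int] = None):
        self.interactions = interactions
        self.random_state = random_state

    def _check_resources(self) -> None:
        if self.interactions is None:
            raise ValueError("InteractionNeighborClassifier requires interactions=")

    def _neighbors(self, x) -> Optional[NeighborSet]:
        return nearest_by_interaction(self.interactions, x, self._training_records())

    @staticmethod
    def features_of(record: DrugRecord):
        return record.drug_id

    def _record_of(self, i: int, x, group: str) -> DrugRecord:
        # x *is* the drug id for this backend; terms are irrelevant here
        return DrugRecord(x, group, frozenset({"-"}))


def predict(
    query_id: str,
    train: TrainingSet,
    *,
    query_terms: Optional[Iterable[str]] = None,
    graph: Optional[OntologyGraph] = None,
    interactions: Optional[InteractionTable] = None,
    backend: str = "ontology",
    seed: Optional[int] = None,
) -> Prediction:
    """One-shot prediction for a single query drug.

    ``backend="ontology"`` needs ``graph`` and ``query_terms``;
    ``backend="interaction"`` needs ``interactions`` (the query is looked up
    by ``query_id``).  Deterministic given identical inputs and seed.
    """
    if backend == "ontology":
        if graph is None or query_terms is None:
            raise ValueError("ontology backend requires graph= and query_terms=")
        clf = OntologyNeighborClassifier(graph=graph, random_state=seed)
        clf.fit_records(train)
        return clf.predict_detail([frozenset(query_terms)], drug_ids=[query_id])[0]
    if backend == "interaction":
        if interactions is None:
            raise ValueError("interaction backend requires interactions=")
        clf = InteractionNeighborClassifier(
            interactions=interactions, random_state=seed
        )
        clf.fit_records(train)
        return clf.predict_detail([query_id], drug_ids=[query_id])[0]
    raise ValueError(f"unknown backend {backend!r}")
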
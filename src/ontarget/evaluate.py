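"""Jackknife and independent-test evaluation with per-group accuracy reports.

The jackknife (leave-one-out) protocol predicts each drug of a dataset from a
model fitted on all the *other* drugs, so the test sample is never part of
its own reference set; the independent-test protocol predicts a held-out
partition against a fixed training partition.  Both produce the same report:
correct/total counts per target group plus overall, with abstentions
(no-prediction outcomes) counted as incorrect and tallied separately.

All accuracy arithmetic is done on integer counts; percentages exist only at
formatting time, so the overall accuracy is exactly the count-weighted mean
of the per-group accuracies.

Tie-break randomness is controlled by one master seed: the i-th query uses a
generator seeded with ``(derived_seed, i)`` where ``derived_seed`` is spawned
deterministically from the master, making every individual prediction
re-runnable in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO

import numpy as np

from .data import TrainingSet

__all__ = [
    "GroupStats",
    "EvaluationReport",
    "jackknife",
    "independent_test",
    "write_report",
    "read_report",
]


def _derived_seed(master: int, index: int) -> int:
    """Per-query tie-break seed, deterministic in (master, index), < 2**31."""
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class GroupStats:
    """Correct/total counts for one target group."""

    n_correct: int
    n_total: int

    @property
    def accuracy(self) -> float | None:
        """Proportion correct, or ``None`` for an empty group."""
        if self.n_total == 0:
            return None
        return self.n_correct / self.n_total


@dataclass
class EvaluationReport:
    """Per-group and overall prediction accuracy for one evaluation run."""

    per_group: dict[str, GroupStats]
    n_no_prediction: int
    protocol: str  # "jackknife" | "independent_test"
    seed: int
    backend: str = ""

    @property
    def overall(self) -> GroupStats:
        return GroupStats(
            n_correct=sum(s.n_correct for s in self.per_group.values()),
            n_total=sum(s.n_total for s in self.per_group.values()),
        )

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "backend": self.backend,
            "seed": self.seed,
            "n_no_prediction": self.n_no_prediction,
            "per_group": {
                g: {"n_correct": s.n_correct, "n_total": s.n_total}
                for g, s in self.per_group.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            per_group={
                g: GroupStats(v["n_correct"], v["n_total"])
                for g, v in d["per_group"].items()
            },
            n_no_prediction=d["n_no_prediction"],
            protocol=d["protocol"],
            seed=d["seed"],
            backend=d.get("backend", ""),
        )


def _fresh(classifier):
    """A new unfitted estimator with the same parameters.

    Parameters are shared by reference (not deep-copied) so the ontology
    graph's memoized distances persist across the evaluation loop.
    """
    return type(classifier)(**classifier.get_params())


def _tally(predictions, truths, groups, protocol, seed, backend):
    correct = {g: 0 for g in groups}
    total = {g: 0 for g in groups}
    n_abstain = 0
    for pred, truth in zip(predictions, truths):
        total[truth] += 1
        if pred.abstained:
            n_abstain += 1  # abstentions count as incorrect
        elif pred.predicted_group == truth:
            correct[truth] += 1
    return EvaluationReport(
        per_group={g: GroupStats(correct[g], total[g]) for g in groups},
        n_no_prediction=n_abstain,
        protocol=protocol,
        seed=seed,
        backend=backend,
    )


def jackknife(dataset: TrainingSet, classifier, seed: int = 0) -> EvaluationReport:
    """Leave-one-out evaluation of a neighbor-vote classifier.

    For each of the n records in turn, the classifier is refitted on the
    other n − 1 records and queried with the held-out drug; the prediction is
    correct iff it equals the held-out record's group.  Exactly n predictions
    are made, and the held-out record is asserted absent from each reference
    set.

    ``classifier`` is an unfitted estimator prototype carrying its backend
    resources, e.g. ``OntologyNeighborClassifier(graph=g)``; its own
    ``random_state`` is ignored in favor of per-query seeds derived from
    ``seed``.
    """
    if len(dataset) < 2 or len(dataset.groups) < 2:
        raise ValueError(
            "jackknife needs at least 2 records and 2 distinct groups, got "
            f"{len(dataset)} records in {len(dataset.groups)} group(s)"
        )
    records = dataset.records
    predictions = []
    for i, held_out in enumerate(records):
        rest = TrainingSet(records[:i] + records[i + 1:])
        assert held_out.drug_id not in set(rest.drug_ids)
        clf = _fresh(classifier)
        clf.random_state = _derived_seed(seed, i)
        clf.fit_records(rest)
        predictions.append(
            clf.predict_detail(
                [type(classifier).features_of(held_out)],
                drug_ids=[held_out.drug_id],
            )[0]
        )
    return _tally(
        predictions, [r.group for r in records], dataset.groups,
        protocol="jackknife", seed=seed, backend=type(classifier).__name__,
    )


def independent_test(
    train: TrainingSet, test: TrainingSet, classifier, seed: int = 0
) -> EvaluationReport:
    """Predict a held-out partition against a fixed training partition.

    ``train`` and ``test`` must be disjoint by drug id; each test record is
    predicted against the full training set.  The i-th test query's
    tie-break seed derives from ``seed`` and i.
    """
    overlap = sorted(set(train.drug_ids) & set(test.drug_ids))
    if overlap:
        raise ValueError(f"train and test sets overlap on drug ids: {overlap}")
    clf = _fresh(classifier)
    clf.random_state = _derived_seed(seed, 0)
    clf.fit_records(train)
    predictions = clf.predict_detail(
        [type(classifier).features_of(r) for r in test],
        drug_ids=test.drug_ids,
    )
    groups = list(dict.fromkeys(train.groups + test.groups))
    return _tally(
        predictions, [r.group for r in test], groups,
        protocol="independent_test", seed=seed,
        backend=type(classifier).__name__,
    )


def _pct(stats: GroupStats) -> str:
    if stats.n_total == 0:
        return "n/a"
    return f"{100.0 * stats.n_correct / stats.n_total:.2f}%"


def write_report(report: EvaluationReport, stream: IO[str]) -> None:
    """Render a report as a human table followed by one machine JSON line.

    Percentages are derived from the stored counts at formatting time and
    are never stored independently; a group with zero samples renders "n/a".
    """
    width = max([len("Target group")] +
                [len(g) for g in report.per_group] + [len("Overall")])
    header = f"{'Target group':<{width}}  {'Correct':>9}  {'Accuracy':>8}"
    stream.write(f"Protocol: {report.protocol}"
                 + (f" ({report.backend})" if report.backend else "")
                 + f", seed {report.seed}\n")
    stream.write(header + "\n")
    stream.write("-" * len(header) + "\n")
    for g, s in report.per_group.items():
        stream.write(
            f"{g:<{width}}  {s.n_correct:>4}/{s.n_total:<4}  {_pct(s):>8}\n"
        )
    o = report.overall
    stream.write(
        f"{'Overall':<{width}}  {o.n_correct:>4}/{o.n_total:<4}  {_pct(o):>8}\n"
    )
    stream.write(f"No-prediction outcomes: {report.n_no_prediction}\n")
    stream.write(json.dumps(report.to_dict(), sort_keys=True) + "\n")


def read_report(stream: IO[str]) -> EvaluationReport:
    """Recover a report from the machine JSON line written by `write_report`."""
    for line in reversed(stream.read().splitlines()):
        line = line.strip()
        if line.startswith("{"):
            return EvaluationReport.from_dict(json.loads(line))
    raise ValueError("no JSON report line found in stream")
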
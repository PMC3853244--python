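"""Labeled drug tables, benchmark filtering, splits, and interaction tables.

A labeled drug table maps each drug id to one target group (the class of
proteins it acts on) and a non-empty set of ontology term ids.  The default
target-group label set is the four KEGG-style groups used throughout this
package; any other finite label set can be configured per dataset.

An interaction table is a sparse symmetric map of STITCH-style combined
interaction scores: a stored score is strictly positive, and an absent pair
means the two chemicals are non-interactive (score 0).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GROUPS",
    "DrugRecord",
    "TrainingSet",
    "FilterCounts",
    "InteractionTable",
    "DrugTableError",
    "read_drug_table",
    "write_drug_table",
    "apply_benchmark_filters",
    "split_train_test",
    "read_interactions",
    "write_interactions",
]

#: Default target-group labels (drug target classes).
DEFAULT_GROUPS: tuple[str, ...] = (
    "G Protein-coupled Receptors",
    "Nuclear Receptors",
    "Ion Channels",
    "Enzymes",
)


class DrugTableError(ValueError):
    """Raised when a drug table violates its invariants."""


@dataclass(frozen=True)
class DrugRecord:
    """One labeled drug: id, single target group, non-empty ontology term set."""

    drug_id: str
    group: str
    terms: frozenset[str]

    def __post_init__(self):
        if not self.drug_id:
            raise DrugTableError("drug_id must be non-empty")
        if not self.terms:
            raise DrugTableError(f"drug {self.drug_id!r} has an empty term set")
        object.__setattr__(self, "terms", frozenset(self.terms))


@dataclass
class TrainingSet:
    """An ordered collection of drug records with unique ids.

    Serves both as a full benchmark dataset and as the reference collection
    a query drug is scored against.
    """

    records: list[DrugRecord] = field(default_factory=list)

    def __post_init__(self):
        self.records = list(self.records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.drug_id in seen:
                raise DrugTableError(f"duplicate drug_id {rec.drug_id!r}")
            seen.add(rec.drug_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def drug_ids(self) -> list[str]:
        return [rec.drug_id for rec in self.records]

    @property
    def group_counts(self) -> dict[str, int]:
        return dict(Counter(rec.group for rec in self.records))

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        return list(dict.fromkeys(rec.group for rec in self.records))


@dataclass(frozen=True)
class FilterCounts:
    """Per-filter rejection tally from :func:`apply_benchmark_filters`."""

    no_terms: int
    multi_group: int
    excluded_group: int

    @property
    def total(self) -> int:
        return self.no_terms + self.multi_group + self.excluded_group


def read_drug_table(
    stream: IO[str] | str,
    groups: Sequence[str] | None = DEFAULT_GROUPS,
) -> TrainingSet:
    """Read a TSV drug table: columns ``drug_id``, ``group``, ``terms``.

    ``terms`` holds semicolon-separated ontology term ids.  A header row is
    required.  ``groups`` restricts the admissible group labels; pass ``None``
    to accept any label.  Rows violating the record invariants are rejected
    with their (1-based, data) row numbers.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    required = {"drug_id", "group", "terms"}
    missing = required - set(df.columns)
    if missing:
        raise DrugTableError(f"drug table missing columns: {sorted(missing)}")
    allowed = set(groups) if groups is not None else None
    records: list[DrugRecord] = []
    seen: set[str] = set()
    for row_number, row in enumerate(df.itertuples(index=False), start=1):
        drug_id, group = row.drug_id, row.group
        if drug_id in seen:
            raise DrugTableError(f"row {row_number}: duplicate drug_id {drug_id!r}")
        seen.add(drug_id)
        if allowed is not None and group not in allowed:
            raise DrugTableError(
                f"row {row_number}: unknown group label {group!r} "
                f"(expected one of {sorted(allowed)})"
            )
        terms = frozenset(t for t in row.terms.split(";") if t)
        if not terms:
            raise DrugTableError(f"row {row_number}: drug {drug_id!r} has no terms")
        records.append(DrugRecord(drug_id, group, terms))
    return TrainingSet(records)


def write_drug_table(s: TrainingSet, stream: IO[str]) -> None:
    """Write a TSV drug table readable by :func:`read_drug_table`."""
    stream.write("drug_id\tgroup\tterms\n")
    for rec in s:
        stream.write(f"{rec.drug_id}\t{rec.group}\t{';'.join(sorted(rec.terms))}\n")


def apply_benchmark_filters(
    raw: Iterable[tuple[str, Iterable[str], Iterable[str]]],
    excluded_groups: Iterable[str] = (),
) -> tuple[TrainingSet, FilterCounts]:
    """Apply the three benchmark-construction filters, in order.

    ``raw`` rows are ``(drug_id, groups, terms)`` where ``groups`` may hold
    zero or several labels.  A record survives only if it (1) has at least
    one ontology term, (2) belongs to exactly one group, and (3) that group
    is not excluded.  Filtering is total: nothing raises, and the per-filter
    rejection counts are returned alongside the survivors.
    """
    excluded = set(excluded_groups)
    no_terms = multi_group = excluded_group = 0
    survivors: list[DrugRecord] = []
    for drug_id, group_labels, terms in raw:
        terms = frozenset(terms)
        group_labels = set(group_labels)
        if not terms:
            no_terms += 1
            continue
        if len(group_labels) != 1:
            multi_group += 1
            continue
        (group,) = group_labels
        if group in excluded:
            excluded_group += 1
            continue
        survivors.append(DrugRecord(drug_id, group, terms))
    return TrainingSet(survivors), FilterCounts(no_terms, multi_group, excluded_group)


def split_train_test(
    s: TrainingSet, test_fraction: float, seed: int
) -> tuple[TrainingSet, TrainingSet]:
    """Randomly partition a dataset into (train, test).

    The test size is round-half-up of ``test_fraction * len(s)`` (e.g. 876
    records at fraction 0.10 give 88), drawn uniformly without replacement;
    record order within each part follows the input.  The same seed always
    reproduces the same partition.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n = len(s)
    n_test = int(np.floor(test_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    train = [rec for i, rec in enumerate(s) if i not in test_idx]
    test = [rec for i, rec in enumerate(s) if i in test_idx]
    return TrainingSet(train), TrainingSet(test)


class InteractionTable:
    """Sparse symmetric chemical-chemical interaction scores.

    ``score(a, b)`` returns the stored positive combined score, or 0 when the
    pair is absent (non-interactive chemicals).
    """

    def __init__(self, scores: Mapping[tuple[str, str], float] | None = None):
        self._scores: dict[tuple[str, str], float] = {}
        if scores:
            for (a, b), value in scores.items():
                self.add(a, b, value)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, value: float) -> None:
        if value <= 0:
            raise ValueError(
                f"stored interaction scores must be > 0, got {value} for ({a}, {b})"
            )
        self._scores[self._key(a, b)] = float(value)

    def score(self, a: str, b: str) -> float:
        return self._scores.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._scores)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self._scores

    def items(self):
        return self._scores.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, InteractionTable) and self._scores == other._scores


def read_interactions(
    stream: IO[str] | str, score_column: str = "combined_score"
) -> InteractionTable:
    """Read a STITCH-style TSV of chemical pairs and scores.

    The first two columns name the chemicals; ``score_column`` selects which
    score defines interactivity.  Rows with score <= 0 are dropped (the pair
    stays non-interactive).  Duplicate rows for the same unordered pair must
    agree; on conflict the larger score is kept with a warning.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    if score_column not in df.columns:
        raise ValueError(
            f"score column {score_column!r} not in file columns {list(df.columns)}"
        )
    score_pos = list(df.columns).index(score_column)
    table = InteractionTable()
    for row_number, row in enumerate(
        df.itertuples(index=False, name=None), start=1
    ):
        raw = row[score_pos]
        try:
            value = float(raw)
        except ValueError:
            raise ValueError(
                f"row {row_number}: non-numeric score {raw!r} in {score_column!r}"
            ) from None
        if value <= 0:
            continue
        a, b = row[0], row[1]
        existing = table.score(a, b)
        if existing and existing != value:
            warnings.warn(
                f"row {row_number}: conflicting scores for pair ({a}, {b}): "
                f"{existing} vs {value}; keeping the larger",
                stacklevel=2,
            )
            value = max(existing, value)
        table.add(a, b, value)
    return table


def write_interactions(table: InteractionTable, stream: IO[str]) -> None:
    """Write one row per unordered pair, STITCH-style column names."""
    stream.write("chemical1\tchemical2\tcombined_score\n")
    for (a, b), value in sorted(table.items()):
        text = f"{value:g}"
        stream.write(f"{a}\t{b}\t{text}\n")
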
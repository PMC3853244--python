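"""Self-contained synthetic fixtures: ontologies, drug tables, interactions.

The generator emulates the structure the predictors exploit in real data:

* an ontology whose term graph is a rooted tree with one branch per target
  group (branches join only at the root, so same-branch terms are closer to
  each other than to any other branch's terms), plus a few relationship-typed
  shortcut edges within branches;
* drugs annotated with terms drawn from their group's branch, with a
  configurable fraction receiving one off-branch noise term;
* a sparse symmetric interaction table where within-group pairs interact
  much more often than cross-group pairs, echoing the premise that
  interactive compounds share features.

Everything is deterministic per seed: regenerating with the same
configuration yields byte-identical files.  The generator makes no attempt
to mimic a real ontology's degree distribution or a real interaction
database's score distribution — class signal is encoded structurally through
branch membership.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import DEFAULT_GROUPS

__all__ = [
    "GeneratorConfig",
    "generate_synthetic_ontology",
    "generate_synthetic_drugs",
    "generate_synthetic_interactions",
    "generate_benchmark",
]

#: STITCH-like combined scores are integers in [150, 999].
_SCORE_LOW, _SCORE_HIGH = 150, 999


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the synthetic benchmark.

    Defaults define the package's standard desk-scale benchmark: 4 target
    groups of 50 drugs each over a 4-branch ontology, 5% of drugs carrying
    one off-branch term, and interactions concentrated within groups.
    """

    n_groups: int = 4
    terms_per_branch: int = 12       # leaf terms per branch
    drugs_per_group: int = 50
    terms_per_drug: int = 2
    branch_depth: int = 3            # hops from root to a leaf
    cross_branch_noise: float = 0.05
    interaction_within_group_rate: float = 0.3
    interaction_cross_group_rate: float = 0.005
    seed: int = 7

    def __post_init__(self):
        for name in ("n_groups", "terms_per_branch", "drugs_per_group",
                     "terms_per_drug", "branch_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("cross_branch_noise", "interaction_within_group_rate",
                     "interaction_cross_group_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def group_labels(self) -> tuple[str, ...]:
        """The four standard target-group labels, or generic ones beyond 4."""
        if self.n_groups <= len(DEFAULT_GROUPS):
            return DEFAULT_GROUPS[: self.n_groups]
        return tuple(
            list(DEFAULT_GROUPS)
            + [f"Group {i + 1}" for i in range(len(DEFAULT_GROUPS), self.n_groups)]
        )


def _term_id(index: int) -> str:
    return f"SYN:{index:07d}"


def generate_synthetic_ontology(
    cfg: GeneratorConfig,
) -> tuple[str, list[tuple[str, str, str]], dict[str, str]]:
    """Build a branch-per-group ontology as OBO 1.2 text.

    Each branch is a spine of ``branch_depth - 1`` intermediate terms hanging
    off the root, with ``terms_per_branch`` leaf terms attached to the
    deepest spine node (directly to the root when depth is 1), so every leaf
    sits ``branch_depth`` hops from the root and branches meet only at the
    root.  One within-branch ``related_to`` relationship shortcut is added
    per branch with at least two leaves.

    Returns
    -------
    (obo_text, edges, branch_map)
        ``edges`` is the ground-truth list of ``(child, parent, relation)``
        assertions; ``branch_map`` maps each non-root term to its group
        label (leaf and spine terms alike).
    """
    rng = np.random.default_rng([cfg.seed, 0])
    root = _term_id(0)
    next_index = 1
    stanzas: dict[str, list[str]] = {root: []}
    edges: list[tuple[str, str, str]] = []
    branch_map: dict[str, str] = {}
    leaves_by_group: dict[str, list[str]] = {}
    for label in cfg.group_labels:
        parent = root
        for _ in range(cfg.branch_depth - 1):
            spine = _term_id(next_index)
            next_index += 1
            stanzas[spine] = [f"is_a: {parent}"]
            edges.append((spine, parent, "is_a"))
            branch_map[spine] = label
            parent = spine
        leaves = []
        for _ in range(cfg.terms_per_branch):
            leaf = _term_id(next_index)
            next_index += 1
            stanzas[leaf] = [f"is_a: {parent}"]
            edges.append((leaf, parent, "is_a"))
            branch_map[leaf] = label
            leaves.append(leaf)
        leaves_by_group[label] = leaves
    # within-branch shortcuts; cross-branch separation is untouched
    for label in cfg.group_labels:
        leaves = leaves_by_group[label]
        if len(leaves) >= 2:
            a, b = rng.choice(len(leaves), size=2, replace=False)
            stanzas[leaves[a]].append(f"relationship: related_to {leaves[b]}")
            edges.append((leaves[a], leaves[b], "related_to"))
    out = io.StringIO()
    out.write("format-version: 1.2\nontology: syn\n")
    for term in sorted(stanzas):
        out.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
        for line in stanzas[term]:
            out.write(line + "\n")
    return out.getvalue(), edges, branch_map


def generate_synthetic_drugs(cfg: GeneratorConfig, branch_map: dict[str, str]) -> str:
    """Drug table TSV: ``drugs_per_group`` drugs per group, branch-drawn terms.

    Each drug samples ``terms_per_drug`` distinct terms from its group's
    branch; a ``cross_branch_noise`` fraction of drugs additionally receives
    one term from another branch.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    terms_by_group: dict[str, list[str]] = {}
    for term, label in branch_map.items():
        terms_by_group.setdefault(label, []).append(term)
    for label in cfg.group_labels:
        pool = terms_by_group.get(label, [])
        if len(pool) < cfg.terms_per_drug:
            raise ValueError(
                f"branch for {label!r} has {len(pool)} terms, fewer than "
                f"terms_per_drug={cfg.terms_per_drug}"
            )
    lines = ["drug_id\tgroup\tterms"]
    drug_number = 0
    for label in cfg.group_labels:
        pool = sorted(terms_by_group[label])
        other_pool = sorted(
            t for t, lab in branch_map.items() if lab != label
        )
        for _ in range(cfg.drugs_per_group):
            drug_number += 1
            picks = rng.choice(len(pool), size=cfg.terms_per_drug, replace=False)
            terms = {pool[int(i)] for i in picks}
            if other_pool and rng.random() < cfg.cross_branch_noise:
                terms.add(other_pool[int(rng.integers(len(other_pool)))])
            lines.append(f"D{drug_number:05d}\t{label}\t{';'.join(sorted(terms))}")
    return "\n".join(lines) + "\n"


def generate_synthetic_interactions(cfg: GeneratorConfig, drug_table: str) -> str:
    """Interaction TSV over the drug table's drugs, one row per scored pair.

    Every unordered pair gets a positive combined score with probability
    ``interaction_within_group_rate`` (same group) or
    ``interaction_cross_group_rate`` (different groups); scores are uniform
    integers in [150, 999].  Unscored pairs are non-interactive (score 0,
    absent from the file).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    drugs: list[tuple[str, str]] = []
    for line in drug_table.splitlines()[1:]:
        if line.strip():
            drug_id, group, _ = line.split("\t")
            drugs.append((drug_id, group))
    lines = ["chemical1\tchemical2\tcombined_score"]
    for i in range(len(drugs)):
        for j in range(i + 1, len(drugs)):
            (a, ga), (b, gb) = drugs[i], drugs[j]
            rate = (
                cfg.interaction_within_group_rate
                if ga == gb
                else cfg.interaction_cross_group_rate
            )
            if rng.random() < rate:
                score = int(rng.integers(_SCORE_LOW, _SCORE_HIGH + 1))
                lines.append(f"{a}\t{b}\t{score}")
    return "\n".join(lines) + "\n"


def generate_benchmark(cfg: GeneratorConfig | None = None):
    """Convenience bundle: (obo_text, drug_table, interaction_tsv, truth).

    ``truth`` is a dict holding the ground-truth edge list and branch map.
    """
    cfg = cfg or GeneratorConfig()
    obo_text, edges, branch_map = generate_synthetic_ontology(cfg)
    drug_table = generate_synthetic_drugs(cfg, branch_map)
    interactions = generate_synthetic_interactions(cfg, drug_table)
    truth = {"edges": edges, "branch_map": branch_map}
    return obo_text, drug_table, interactions, truth
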
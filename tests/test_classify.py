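"""Neighbor searches, majority voting, and the end-to-end predictors."""

import io
from fractions import Fraction

import numpy as np
import pytest
from sklearn.base import clone

from ontarget import (
    DEFAULT_GROUPS,
    InteractionNeighborClassifier,
    InteractionTable,
    NeighborSet,
    OntologyNeighborClassifier,
    nearest_by_interaction,
    nearest_by_ontology,
    parse_obo,
    predict,
    vote,
)

from conftest import (
    floyd_warshall_oracle,
    neighbor_scenario_obo,
    random_graph_instance,
    training_set_from_rows,
)

GPCR, NUCLEAR, ION, ENZYME = DEFAULT_GROUPS


# ---------------------------------------------------------------------------
# nearest_by_ontology


class TestNearestByOntology:
    def test_identical_terms_are_the_unique_nearest_neighbor(self, chain_graph):
        train = training_set_from_rows([
            ("D1", GPCR, "A"), ("D2", ENZYME, "C"),
        ])
        ns = nearest_by_ontology(chain_graph, {"A"}, train)
        assert [r.drug_id for r in ns.records] == ["D1"]
        assert ns.score == 0

    def test_equidistant_neighbors_all_returned_farther_excluded(self):
        near = [f"N{i}" for i in range(5)]
        far = [f"F{i}" for i in range(3)]
        g = parse_obo(io.StringIO(neighbor_scenario_obo("QT", near, far)))
        train = training_set_from_rows(
            [(f"D{i}", GPCR, t) for i, t in enumerate(near + far)]
        )
        ns = nearest_by_ontology(g, {"QT"}, train)
        assert sorted(r.drug_id for r in ns.records) == [f"D{i}" for i in range(5)]
        assert ns.score == Fraction(2)

    def test_undefined_scores_are_skipped_and_may_abstain(self):
        import networkx as nx

        from ontarget import OntologyGraph

        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("Z")
        og = OntologyGraph(g)
        train = training_set_from_rows([("D1", GPCR, "Z"), ("D2", ION, "B")])
        ns = nearest_by_ontology(og, {"A"}, train)
        assert [r.drug_id for r in ns.records] == ["D2"]
        only_z = training_set_from_rows([("D1", GPCR, "Z")])
        assert nearest_by_ontology(og, {"A"}, only_z) is None

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g, names, edges, n = random_graph_instance(seed + 1000, max_nodes=25)
        oracle = floyd_warshall_oracle(n, edges)
        idx = {t: i for i, t in enumerate(names)}
        n_drugs = int(rng.integers(3, 41))
        rows = []
        for d in range(n_drugs):
            terms = rng.choice(
                names, size=min(n, int(rng.integers(1, 4))), replace=False
            )
            rows.append((f"D{d}", DEFAULT_GROUPS[d % 4], set(terms.tolist())))
        train = training_set_from_rows(rows)
        query = set(
            rng.choice(
                names, size=min(n, int(rng.integers(1, 4))), replace=False
            ).tolist()
        )
        # independent scan over the oracle matrix
        best, argmin = None, []
        for drug_id, _, terms in rows:
            dists = [oracle[idx[a], idx[b]] for a in query for b in terms]
            if np.isinf(dists).any():
                continue
            q = Fraction(int(sum(dists)), len(dists))
            if best is None or q < best:
                best, argmin = q, [drug_id]
            elif q == best:
                argmin.append(drug_id)
        ns = nearest_by_ontology(g, query, train)
        if best is None:
            assert ns is None
        else:
            assert sorted(r.drug_id for r in ns.records) == sorted(argmin)
            assert ns.score == best


# ---------------------------------------------------------------------------
# nearest_by_interaction


class TestNearestByInteraction:
    def test_single_positive_partner_wins(self):
        train = training_set_from_rows([("D1", GPCR, "x"), ("D2", ION, "x")])
        table = InteractionTable({("Q", "D2"): 400})
        ns = nearest_by_interaction(table, "Q", train)
        assert [r.drug_id for r in ns.records] == ["D2"]

    def test_no_interacting_training_drug_means_no_prediction(self):
        train = training_set_from_rows([("D1", GPCR, "x")])
        assert nearest_by_interaction(InteractionTable(), "Q", train) is None

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_argmax_scan(self, seed):
        rng = np.random.default_rng(seed)
        n_drugs = int(rng.integers(2, 40))
        rows = [(f"D{d}", DEFAULT_GROUPS[d % 4], "x") for d in range(n_drugs)]
        train = training_set_from_rows(rows)
        table = InteractionTable()
        scores = {}
        for d in range(n_drugs):
            if rng.random() < 0.4:
                s = float(rng.integers(1, 8))  # coarse scores force ties
                table.add("Q", f"D{d}", s)
                scores[f"D{d}"] = s
        ns = nearest_by_interaction(table, "Q", train)
        if not scores:
            assert ns is None
        else:
            best = max(scores.values())
            assert sorted(r.drug_id for r in ns.records) == sorted(
                d for d, s in scores.items() if s == best
            )


# ---------------------------------------------------------------------------
# voting


class TestVote:
    def test_majority_wins_without_tie_break(self):
        rows = [(f"D{i}", GPCR, "x") for i in range(11)]
        rows += [(f"E{i}", ENZYME, "x") for i in range(2)]
        train = training_set_from_rows(rows)
        ns = NeighborSet(tuple((r, Fraction(2)) for r in train), criterion="min_Q")
        pred = vote(ns, seed=0)
        assert pred.votes == {GPCR: 11, ENZYME: 2}
        assert pred.predicted_group == GPCR
        assert pred.tie_broken is False
        assert sum(pred.votes.values()) == len(ns)

    def test_tie_break_is_seeded_and_roughly_uniform(self):
        train = training_set_from_rows([("D1", GPCR, "x"), ("D2", ION, "x")])
        ns = NeighborSet(tuple((r, Fraction(1)) for r in train), criterion="min_Q")
        first = vote(ns, seed=42)
        assert first.tie_broken is True
        assert all(vote(ns, seed=42).predicted_group == first.predicted_group
                   for _ in range(5))
        wins = sum(vote(ns, seed=s).predicted_group == GPCR for s in range(2000))
        # binomial(2000, 1/2): mean 1000, sd ~22.4; allow 5 sd
        assert abs(wins - 1000) < 112

    def test_unequal_scores_rejected(self):
        train = training_set_from_rows([("D1", GPCR, "x"), ("D2", ION, "x")])
        with pytest.raises(ValueError, match="not all equal"):
            NeighborSet(
                ((train.records[0], Fraction(1)), (train.records[1], Fraction(2))),
                criterion="min_Q",
            )


# ---------------------------------------------------------------------------
# end-to-end predict and estimator behavior


class TestPredict:
    def scenario(self):
        near = [(f"D{i}", GPCR) for i in range(4)] + [("E0", ENZYME)]
        far = [(f"F{i}", ION) for i in range(3)]
        obo = neighbor_scenario_obo(
            "QT", [f"T{d}" for d, _ in near], [f"T{d}" for d, _ in far]
        )
        g = parse_obo(io.StringIO(obo))
        train = training_set_from_rows(
            [(d, grp, f"T{d}") for d, grp in near + far]
        )
        return g, train

    def test_composition_of_search_and_vote(self):
        g, train = self.scenario()
        pred = predict("Q1", train, query_terms={"QT"}, graph=g, seed=0)
        assert pred.predicted_group == GPCR
        assert pred.votes == {GPCR: 4, ENZYME: 1}
        assert pred.tie_broken is False
        assert len(pred.neighbors) == 5

    def test_interaction_backend_and_abstention(self):
        _, train = self.scenario()
        table = InteractionTable({("Q1", "E0"): 800})
        pred = predict("Q1", train, interactions=table, backend="interaction")
        assert pred.predicted_group == ENZYME
        lonely = predict("QX", train, interactions=table, backend="interaction")
        assert lonely.abstained and lonely.predicted_group is None

    def test_training_order_invariance(self):
        g, train = self.scenario()
        reversed_train = training_set_from_rows(
            [(r.drug_id, r.group, set(r.terms)) for r in reversed(train.records)]
        )
        a = predict("Q1", train, query_terms={"QT"}, graph=g, seed=5)
        b = predict("Q1", reversed_train, query_terms={"QT"}, graph=g, seed=5)
        assert a.predicted_group == b.predicted_group
        assert a.votes == b.votes

    def test_term_twin_in_training_set_wins_or_ties(self):
        g, train = self.scenario()
        twin = training_set_from_rows(
            [(r.drug_id, r.group, set(r.terms)) for r in train.records]
            + [("TWIN", NUCLEAR, {"QT"})]
        )
        pred = predict("Q1", twin, query_terms={"QT"}, graph=g, seed=0)
        assert pred.predicted_group == NUCLEAR  # Q = 0 dominates everything
        assert pred.neighbors.score == 0


class TestEstimatorProtocol:
    def test_get_params_clone_and_refit(self, chain_graph):
        clf = OntologyNeighborClassifier(graph=chain_graph, random_state=3)
        assert clf.get_params()["random_state"] == 3
        cloned = clone(clf)
        cloned.fit([{"A"}, {"C"}], [GPCR, ION])
        assert list(cloned.classes_) == sorted([GPCR, ION])
        assert cloned.predict([{"C"}])[0] == ION

    def test_unfitted_predict_raises(self, chain_graph):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            OntologyNeighborClassifier(graph=chain_graph).predict([{"A"}])

    def test_missing_resources_rejected_at_fit(self):
        with pytest.raises(ValueError, match="graph"):
            OntologyNeighborClassifier().fit([{"A"}], [GPCR])
        with pytest.raises(ValueError, match="interactions"):
            InteractionNeighborClassifier().fit(["D1"], [GPCR])
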
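"""Term graphs from OBO ontologies and hop distances between terms.

A chemical ontology (e.g. ChEBI) is read as an undirected graph whose nodes
are ontology terms and whose edges are the ``is_a`` and ``relationship``
assertions between terms.  The hop distance between two terms on this graph
is the elementary notion of relatedness everything downstream builds on: the
fewer edges separate two terms, the more intimately they are related.

Direction of ``is_a`` is deliberately discarded and parallel assertions
between the same two terms (e.g. an ``is_a`` plus a ``has_role``) collapse to
a single edge, because the distance is used symmetrically and unweighted.
"""

from __future__ import annotations

import io
import os
from typing import IO, Iterator

import networkx as nx
import obonet

__all__ = [
    "OboParseError",
    "UnknownTermError",
    "OntologyGraph",
    "parse_obo",
    "term_distance",
]


class OboParseError(ValueError):
    """Raised when an OBO stanza cannot be interpreted."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownTermError(KeyError):
    """Raised when a term id is not a node of the ontology graph."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(term)

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"unknown ontology term: {self.term!r}"


def _validate_stanzas(text: str) -> None:
    """Check every [Term] stanza carries an ``id:`` line.

    obonet silently assumes well-formed stanzas; this pre-scan turns a
    missing id into an error that names the offending stanza's line number.
    """
    stanza_line: int | None = None
    saw_id = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("["):
            if stanza_line is not None and not saw_id:
                raise OboParseError("[Term] stanza has no id line", line=stanza_line)
            stanza_line = lineno if line == "[Term]" else None
            saw_id = False
        elif stanza_line is not None and line.startswith("id:"):
            saw_id = True
    if stanza_line is not None and not saw_id:
        raise OboParseError("[Term] stanza has no id line", line=stanza_line)


class OntologyGraph:
    """Undirected term graph with memoized breadth-first hop distances.

    Parameters
    ----------
    graph
        Undirected :class:`networkx.Graph` whose nodes are term id strings.
        Edge attribute ``relations`` (a set of relation labels) records which
        assertions produced each edge; distances ignore it.
    """

    def __init__(self, graph: nx.Graph):
        self._graph = graph
        self._bfs_cache: dict[str, dict[str, int]] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_obo(
        cls, source: str | os.PathLike | IO[str], *, keep_obsolete: bool = True
    ) -> "OntologyGraph":
        """Build a graph from OBO 1.2 text (path, path-like or open stream).

        One node per ``[Term]`` stanza id; one undirected edge per ``is_a``
        and per ``relationship`` line (any relation type), deduplicated per
        unordered pair.  Terms referenced by an edge but lacking a stanza of
        their own still become nodes.  Obsolete terms are kept unless
        ``keep_obsolete=False``.
        """
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        _validate_stanzas(text)
        multi = obonet.read_obo(
            io.StringIO(text), ignore_obsolete=not keep_obsolete
        )
        graph = nx.Graph()
        graph.add_nodes_from(multi.nodes())
        for u, v, relation in multi.edges(keys=True):
            if u == v:
                continue  # self-loops carry no distance information
            if graph.has_edge(u, v):
                graph.edges[u, v]["relations"].add(relation)
            else:
                graph.add_edge(u, v, relations={relation})
        return cls(graph)

    # -- basic queries -----------------------------------------------------

    @property
    def node_count(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self._graph.number_of_edges()

    @property
    def graph(self) -> nx.Graph:
        """The underlying networkx graph (shared, do not mutate)."""
        return self._graph

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def __iter__(self) -> Iterator[str]:
        return iter(self._graph)

    def __repr__(self) -> str:
        return (
            f"{type(self).__name__}(nodes={self.node_count}, "
            f"edges={self.edge_count})"
        )

    # -- distances ---------------------------------------------------------

    def distances_from(self, source: str) -> dict[str, int]:
        """Hop distances from ``source`` to every reachable term (memoized)."""
        if source not in self._graph:
            raise UnknownTermError(source)
        cached = self._bfs_cache.get(source)
        if cached is None:
            cached = dict(nx.single_source_shortest_path_length(self._graph, source))
            self._bfs_cache[source] = cached
        return cached

    def distance(self, t1: str, t2: str) -> int | None:
        """Shortest undirected path length in hops, or ``None`` if unreachable."""
        if t1 not in self._graph:
            raise UnknownTermError(t1)
        if t2 not in self._graph:
            raise UnknownTermError(t2)
        if t1 == t2:
            return 0
        # reuse whichever endpoint is already memoized
        for a, b in ((t1, t2), (t2, t1)):
            cached = self._bfs_cache.get(a)
            if cached is not None:
                return cached.get(b)
        return self.distances_from(t1).get(t2)

    # -- serialization -----------------------------------------------------

    def write_edge_list(self, stream: IO[str]) -> None:
        """Write the edges as two tab-separated term-id columns, sorted."""
        for u, v in sorted(tuple(sorted(e)) for e in self._graph.edges()):
            stream.write(f"{u}\t{v}\n")


def parse_obo(
    source: str | os.PathLike | IO[str], *, keep_obsolete: bool = True
) -> OntologyGraph:
    """Parse an OBO 1.2 file into an :class:`OntologyGraph`.

    An empty stream yields an empty graph; a ``[Term]`` stanza without an
    ``id:`` line raises :class:`OboParseError` naming its line number.
    """
    return OntologyGraph.from_obo(source, keep_obsolete=keep_obsolete)


def term_distance(g: OntologyGraph, t1: str, t2: str) -> int | None:
    """Hop distance between two terms; ``None`` marks an unreachable pair."""
    return g.distance(t1, t2)
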
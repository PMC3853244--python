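"""Functional-relationship score between two compounds' ontology term sets.

The score Q(c1, c2) of two compounds is the arithmetic mean of the graph hop
distance d(t1, t2) over every pair (t1, t2) in the Cartesian product
T(c1) x T(c2) of their ontology term sets.  Smaller Q means a stronger
functional relationship.  The mean is taken over the full product including
repeated distance values (the usual semantic-similarity convention), and is
kept as an exact fraction — an integer distance sum over an integer pair
count — so that downstream minimum-Q neighbor selection compares and ties
exactly, without floating-point epsilon policy.

If any required term pair is unreachable on the graph, Q is *undefined*
(returned as ``None``) rather than infinite: a disconnected ontology
component carries no usable distance evidence, and callers must decide
explicitly what to do (the neighbor search skips undefined candidates).
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Optional

from .ontology import OntologyGraph, UnknownTermError

__all__ = ["compound_similarity"]


def compound_similarity(
    g: OntologyGraph, terms_a: Iterable[str], terms_b: Iterable[str]
) -> Optional[Fraction]:
    """Mean hop distance over all cross pairs of two term sets.

    Parameters
    ----------
    g
        The ontology term graph.
    terms_a, terms_b
        Non-empty collections of term ids, all present in ``g``.

    Returns
    -------
    Fraction or None
        Exact mean distance, or ``None`` when any cross pair is unreachable
        (the score is undefined).

    Raises
    ------
    ValueError
        If either term set is empty.
    UnknownTermError
        If any term is not a node of ``g``.
    """
    set_a = frozenset(terms_a)
    set_b = frozenset(terms_b)
    if not set_a or not set_b:
        raise ValueError("compound_similarity requires two non-empty term sets")
    for term in set_a | set_b:
        if term not in g:
            raise UnknownTermError(term)
    total = 0
    for a in set_a:
        from_a = g.distances_from(a)
        for b in set_b:
            d = from_a.get(b)
            if d is None:
                return None
            total += d
    return Fraction(total, len(set_a) * len(set_b))
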
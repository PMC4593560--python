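"""Ontology parsing and DAG queries.

An ontology (GO, Disease Ontology, ...) is modelled as a directed acyclic
graph of terms with child->parent edges tagged by relation (``is_a``,
``part_of``, ...).  Only edges whose relation is in a configurable whitelist
are traversed; this is the propagation backbone for the true-path rule and
for the term-distinctness queries used by multifunctionality detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relations traversed by default; matches the propagation convention of
#: mainstream GO tooling.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass(frozen=True)
class Term:
    """A single ontology term.

    Obsolete terms are kept as records for diagnostics but never take part
    in traversal.
    """

    id: str
    name: str = ""
    namespace: str = ""
    obsolete: bool = False
    replaced_by: tuple[str, ...] = ()


@dataclass
class OntologyGraph:
    """A validated term DAG with relation-filtered traversal edges.

    ``graph`` holds child->parent edges (one edge per surviving relation);
    ancestors of a term are the nodes reachable *from* it, descendants the
    nodes that reach it.  Multi-rooted files are supported: every operation
    that needs "the root" takes it explicitly.
    """

    terms: dict[str, Term]
    graph: nx.DiGraph  # child -> parent, traversal edges only
    relations: frozenset[str] = DEFAULT_RELATIONS
    _anc_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    _desc_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def _check_traversable(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise KeyError(f"term {term_id!r} not in ontology")
        if self.terms[term_id].obsolete:
            raise ValueError(f"term {term_id!r} is obsolete and not traversable")

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable from ``term_id`` via traversal edges (excl. self)."""
        self._check_traversable(term_id)
        cached = self._anc_cache.get(term_id)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term_id))
            self._anc_cache[term_id] = cached
        return cached

    def descendants(self, term_id: str) -> frozenset[str]:
        """All terms from which ``term_id`` is reachable (excl. self)."""
        self._check_traversable(term_id)
        cached = self._desc_cache.get(term_id)
        if cached is None:
            cached = frozenset(nx.ancestors(self.graph, term_id))
            self._desc_cache[term_id] = cached
        return cached

    def roots(self, namespace: str | None = None) -> frozenset[str]:
        """Non-obsolete terms with no parents, optionally restricted to a namespace."""
        out = []
        for tid, term in self.terms.items():
            if term.obsolete:
                continue
            if namespace is not None and term.namespace != namespace:
                continue
            if self.graph.out_degree(tid) == 0:
                out.append(tid)
        return frozenset(out)

    def namespace_root(self, namespace: str) -> str:
        """The unique root of a namespace; error if absent or ambiguous."""
        roots = self.roots(namespace)
        if len(roots) != 1:
            raise ValueError(
                f"namespace {namespace!r} has {len(roots)} roots ({sorted(roots)}); "
                "pass the intended root explicitly"
            )
        return next(iter(roots))

    def is_disjoint_pair(self, t1: str, t2: str, root: str) -> bool:
        """True iff two terms are distinct in the root-only-LCA sense.

        The pair passes iff (i) their only common ancestor is the namespace
        root, (ii) they share no common descendant, and (iii) neither is an
        ancestor of the other.  Equivalent to "least common ancestor is the
        root" on a DAG, and safe when several common ancestors exist.
        """
        if t1 == t2:
            raise ValueError("is_disjoint_pair requires two distinct terms")
        ns = {self.terms[t].namespace for t in (t1, t2, root)}
        if len(ns) != 1:
            raise ValueError(f"terms {t1}, {t2} and root {root} span namespaces {sorted(ns)}")
        a1, a2 = self.ancestors(t1), self.ancestors(t2)
        if t1 in a2 or t2 in a1:
            return False
        if (a1 & a2) - {root}:
            return False
        if self.descendants(t1) & self.descendants(t2):
            return False
        return True


def load_obo(
    stream: IO[str] | str,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into a validated :class:`OntologyGraph`.

    Parameters
    ----------
    stream:
        File path or open text handle with OBO content.
    relations:
        Relation labels to keep as traversal edges (e.g. ``{"is_a", "part_of"}``).

    Raises
    ------
    ValueError
        If the kept edges contain a cycle (the message names a cycle member)
        or an edge points to an undeclared term.
    """
    relations = frozenset(relations)
    if not relations:
        raise ValueError("relation whitelist must be non-empty")
    multi = obonet.read_obo(stream, ignore_obsolete=False)

    # nodes with no attributes were never declared in a [Term] stanza and
    # exist only as dangling edge targets
    declared = {tid for tid, data in multi.nodes(data=True) if data}
    terms: dict[str, Term] = {}
    for tid, data in multi.nodes(data=True):
        if tid not in declared:
            continue
        replaced = tuple(data.get("replaced_by", ()))
        terms[tid] = Term(
            id=tid,
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
            replaced_by=replaced,
        )

    graph = nx.DiGraph()
    graph.add_nodes_from(tid for tid, t in terms.items() if not t.obsolete)
    for child, parent, rel in multi.edges(keys=True):
        if rel not in relations:
            continue
        if parent not in terms:
            raise ValueError(f"edge {child} -[{rel}]-> {parent}: unknown parent id")
        if terms[child].obsolete or terms[parent].obsolete:
            continue
        graph.add_edge(child, parent, relation=rel)

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"ontology contains a cycle through {cycle[0][0]!r}")

    n_obsolete = sum(t.obsolete for t in terms.values())
    if n_obsolete:
        logger.info("loaded %d terms (%d obsolete, excluded from traversal)", len(terms), n_obsolete)
    return OntologyGraph(terms=terms, graph=graph, relations=relations)


def ancestors(graph: OntologyGraph, term_id: str) -> frozenset[str]:
    return graph.ancestors(term_id)


def descendants(graph: OntologyGraph, term_id: str) -> frozenset[str]:
    return graph.descendants(term_id)


def is_disjoint_pair(graph: OntologyGraph, t1: str, t2: str, root: str) -> bool:
    return graph.is_disjoint_pair(t1, t2, root)
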
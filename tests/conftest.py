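from __future__ import annotations

import networkx as nx
import pytest

from multifun.annotations import AnnotationRecord
from multifun.ontology import OntologyGraph, Term


def make_graph(edges, terms=None, obsolete=(), namespace="biological_process"):
    """Build an OntologyGraph from child->parent is_a edges."""
    nodes = set(terms or [])
    for c, p in edges:
        nodes |= {c, p}
    g = nx.DiGraph()
    g.add_nodes_from(n for n in nodes if n not in obsolete)
    for c, p in edges:
        g.add_edge(c, p, relation="is_a")
    term_map = {
        n: Term(id=n, name=n, namespace=namespace, obsolete=n in obsolete)
        for n in nodes
    }
    return OntologyGraph(terms=term_map, graph=g)


def records_from(gene_terms: dict[str, set[str]]):
    return [
        AnnotationRecord(gene=g, term=t, evidence="EXP", aspect="P")
        for g, ts in sorted(gene_terms.items())
        for t in sorted(ts)
    ]


@pytest.fixture
def diamond():
    """C -> {B1, B2} -> A."""
    return make_graph([("C", "B1"), ("C", "B2"), ("B1", "A"), ("B2", "A")])


@pytest.fixture
def chain():
    """C -> B -> A."""
    return make_graph([("C", "B"), ("B", "A")])
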
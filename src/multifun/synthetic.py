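"""Synthetic fixtures with planted structure.

Generators for ontologies, annotation sets, interaction networks,
orthology maps and feature tables, each fully determined by (parameters,
seed) and written in the same file dialects the loaders read.  The
annotation generator plants a known multifunctional gene set:

* the ontology is a single root over ``n_branches`` disjoint subtrees, so
  any two terms from different branches satisfy the root-only-ancestor
  condition by construction;
* background genes are annotated to a single leaf each, hence their
  propagated terms lie on one root path and no distinct term pair can
  co-annotate them;
* each planted multifunctional gene is annotated to a gene-specific pair
  of leaves from two different branches, with pair assignments balanced so
  every leaf's propagated count stays inside one specificity window and
  no leaf pair's overlap becomes co-annotation-enriched;
* optionally, a flagged decoy term pair in two reserved branches is
  co-annotated by a block of shared genes, making the pair (and its
  ancestor pairs) fail the hypergeometric filter at every level where the
  terms are selected — those genes must never be called through it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .annotations import AnnotationRecord
from .networks import InteractionNetwork
from .ontology import OntologyGraph, Term

NAMESPACE = "biological_process"
_ASPECT = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}


@dataclass
class SyntheticTruth:
    planted_multifunctional: frozenset[str] = frozenset()
    planted_decoy_pair: tuple[str, str] | None = None
    planted_decoy_genes: frozenset[str] = frozenset()
    planted_modules: dict[str, int] = field(default_factory=dict)
    planted_ortholog_excess: float = 1.0
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_multifunctional": sorted(self.planted_multifunctional),
                "planted_decoy_pair": list(self.planted_decoy_pair) if self.planted_decoy_pair else None,
                "planted_decoy_genes": sorted(self.planted_decoy_genes),
                "planted_modules": self.planted_modules,
                "planted_ortholog_excess": self.planted_ortholog_excess,
                "parameters": self.parameters,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# ontology


def gen_ontology(
    n_branches: int = 6,
    depth: int = 2,
    fanout: int = 2,
    seed: int = 0,
    p_crosslink: float = 0.0,
    namespace: str = NAMESPACE,
) -> OntologyGraph:
    """A single-rooted DAG of ``n_branches`` disjoint subtrees.

    Each branch is a balanced tree of the given depth and fanout; with
    ``p_crosslink > 0`` extra within-branch child->parent edges are added
    (never across branches, so cross-branch pairs always have only the
    root as common ancestor).
    """
    if n_branches < 1 or depth < 1 or fanout < 1:
        raise ValueError("n_branches, depth and fanout must be >= 1")
    rng = np.random.default_rng(seed)
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"GO:{counter[0]:07d}"

    terms: dict[str, Term] = {}
    graph = nx.DiGraph()
    root = new_id()
    terms[root] = Term(id=root, name="root process", namespace=namespace)
    graph.add_node(root)

    for b in range(n_branches):
        # per-branch levels of term ids; level 0 is the branch root
        levels: list[list[str]] = []
        branch_root = new_id()
        terms[branch_root] = Term(id=branch_root, name=f"branch {b}", namespace=namespace)
        graph.add_edge(branch_root, root, relation="is_a")
        levels.append([branch_root])
        for d in range(1, depth):
            level: list[str] = []
            for parent in levels[-1]:
                for _ in range(fanout):
                    tid = new_id()
                    terms[tid] = Term(id=tid, name=f"branch {b} level {d}", namespace=namespace)
                    graph.add_edge(tid, parent, relation="is_a")
                    level.append(tid)
            levels.append(level)
        if p_crosslink > 0:
            for d in range(2, depth):
                for tid in levels[d]:
                    if rng.random() < p_crosslink:
                        extra_parent = str(rng.choice(levels[d - 1]))
                        graph.add_edge(tid, extra_parent, relation="is_a")
    return OntologyGraph(terms=terms, graph=graph)


def branch_roots(graph: OntologyGraph, root: str) -> list[str]:
    """Direct children of the root, sorted."""
    return sorted(graph.graph.predecessors(root))


def branch_leaves(graph: OntologyGraph, branch_root: str) -> list[str]:
    """Leaf terms of one branch, sorted."""
    members = {branch_root} | set(graph.descendants(branch_root))
    return sorted(t for t in members if graph.graph.in_degree(t) == 0)


# ---------------------------------------------------------------------------
# annotations


def gen_annotations(
    graph: OntologyGraph,
    n_genes: int = 300,
    planted_mf: int = 25,
    coannotation_enrichment: float = 1.0,
    seed: int = 0,
    background_per_leaf: int = 10,
) -> tuple[list[AnnotationRecord], SyntheticTruth]:
    """Annotation records with a planted multifunctional gene set.

    ``coannotation_enrichment > 1`` reserves the last two branches for a
    decoy term pair co-annotated by ``int(enrichment * background_per_leaf)``
    shared genes; those genes and that pair must be rejected by the
    hypergeometric co-annotation filter.  Genes beyond the planted,
    decoy and per-leaf background populations are annotated to the root
    only (they enlarge the universe without touching term selection).
    """
    rng = np.random.default_rng(seed)
    roots = sorted(graph.roots())
    if len(roots) != 1:
        raise ValueError("gen_annotations expects a single-rooted graph")
    root = roots[0]
    branches = branch_roots(graph, root)
    decoy_on = coannotation_enrichment > 1.0
    if decoy_on and len(branches) < 4:
        raise ValueError("decoy pair needs at least 4 branches")
    if not decoy_on and len(branches) < 2:
        raise ValueError("planting needs at least 2 branches")
    usable = branches[:-2] if decoy_on else branches
    decoy_branches = branches[-2:] if decoy_on else []

    leaves_by_branch = {b: branch_leaves(graph, b) for b in branches}
    usable_leaves = [(b, leaf) for b in usable for leaf in leaves_by_branch[b]]

    n_decoy = int(coannotation_enrichment * background_per_leaf) if decoy_on else 0
    n_decoy_bg = sum(len(leaves_by_branch[b]) - 1 for b in decoy_branches) * background_per_leaf
    required = planted_mf + len(usable_leaves) * background_per_leaf + n_decoy + n_decoy_bg
    if required > n_genes:
        raise ValueError(f"n_genes={n_genes} too small; populations need {required} genes")

    gene_ids = iter(f"g{i:05d}" for i in range(n_genes))
    records: list[AnnotationRecord] = []

    def annotate(gene: str, term: str) -> None:
        records.append(AnnotationRecord(gene=gene, term=term, evidence="EXP", aspect="P"))

    # cross-branch leaf pairs for planting, shuffled then round-robin so
    # per-pair overlap and per-leaf load stay small and balanced
    pairs = [
        (l1, l2)
        for i, (b1, l1) in enumerate(usable_leaves)
        for (b2, l2) in usable_leaves[i + 1:]
        if b1 != b2
    ]
    if planted_mf > 0 and not pairs:
        raise ValueError("no cross-branch leaf pairs available for planting")
    order = rng.permutation(len(pairs))
    leaf_load: dict[str, int] = {leaf: 0 for _, leaf in usable_leaves}
    planted: list[str] = []
    for k in range(planted_mf):
        gene = next(gene_ids)
        l1, l2 = pairs[order[k % len(pairs)]]
        annotate(gene, l1)
        annotate(gene, l2)
        leaf_load[l1] += 1
        leaf_load[l2] += 1
        planted.append(gene)
    if leaf_load and max(leaf_load.values()) >= background_per_leaf:
        raise ValueError(
            "planted load per leaf reaches the background count; "
            "increase branches/fanout or background_per_leaf"
        )

    # background: one leaf each, keeping every usable leaf's propagated
    # count inside [background_per_leaf, 2 * background_per_leaf)
    for _, leaf in usable_leaves:
        for _ in range(background_per_leaf):
            annotate(next(gene_ids), leaf)

    decoy_pair: tuple[str, str] | None = None
    decoy_genes: list[str] = []
    if decoy_on:
        d1 = leaves_by_branch[decoy_branches[0]][0]
        d2 = leaves_by_branch[decoy_branches[1]][0]
        decoy_pair = (d1, d2)
        for _ in range(n_decoy):
            gene = next(gene_ids)
            annotate(gene, d1)
            annotate(gene, d2)
            decoy_genes.append(gene)
        for b in decoy_branches:
            for leaf in leaves_by_branch[b]:
                if leaf in (d1, d2):
                    continue
                for _ in range(background_per_leaf):
                    annotate(next(gene_ids), leaf)

    # filler genes keep the universe at n_genes without touching counts
    for gene in gene_ids:
        annotate(gene, root)

    n_used = len({r.gene for r in records})
    if n_used < len(planted) + len(decoy_genes):  # pragma: no cover - guarded above
        raise ValueError("n_genes too small for requested populations")
    truth = SyntheticTruth(
        planted_multifunctional=frozenset(planted),
        planted_decoy_pair=decoy_pair,
        planted_decoy_genes=frozenset(decoy_genes),
        parameters={
            "n_genes": n_genes,
            "planted_mf": planted_mf,
            "coannotation_enrichment": coannotation_enrichment,
            "background_per_leaf": background_per_leaf,
        },
        seed=seed,
    )
    return records, truth


def gen_random_annotations(
    graph: OntologyGraph,
    n_genes: int = 150,
    max_terms_per_gene: int = 3,
    seed: int = 0,
) -> list[AnnotationRecord]:
    """Unstructured random annotations (for oracle-equivalence fixtures)."""
    rng = np.random.default_rng(seed)
    terms = sorted(t for t, rec in graph.terms.items() if not rec.obsolete)
    records = []
    for i in range(n_genes):
        gene = f"g{i:05d}"
        k = int(rng.integers(1, max_terms_per_gene + 1))
        for t in rng.choice(terms, size=k, replace=False):
            records.append(AnnotationRecord(gene=gene, term=str(t), evidence="EXP", aspect="P"))
    return records


# ---------------------------------------------------------------------------
# networks


def gen_network(
    n_nodes: int = 200,
    n_modules: int = 4,
    p_within: float = 0.25,
    p_between: float = 0.01,
    seed: int = 0,
) -> tuple[InteractionNetwork, dict[str, int]]:
    """A planted-partition (stochastic block model) network over genes."""
    if n_nodes < n_modules:
        raise ValueError("need at least one node per module")
    rng = np.random.default_rng(seed)
    nodes = [f"g{i:05d}" for i in range(n_nodes)]
    module = {nodes[i]: i % n_modules for i in range(n_nodes)}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            p = p_within if module[nodes[i]] == module[nodes[j]] else p_between
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j])
    return InteractionNetwork(graph=g), module


# ---------------------------------------------------------------------------
# orthology


def gen_orthology(
    n_pairs: int = 1000,
    f_mf_a: float = 0.3,
    f_mf_b: float = 0.3,
    excess: float = 1.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], frozenset[str], frozenset[str], SyntheticTruth]:
    """One-to-one ortholog pairs with a controllable both-multifunctional excess.

    ``excess = 1`` assigns multifunctional labels uniformly at random on
    each side (the null); ``excess > 1`` plants exactly
    ``round(excess * n_pairs * f_mf_a * f_mf_b)`` both-multifunctional
    pairs while keeping the per-side label counts at ``f_mf * n_pairs``.
    """
    rng = np.random.default_rng(seed)
    genes_a = [f"a{i:05d}" for i in range(n_pairs)]
    genes_b = [f"b{i:05d}" for i in range(n_pairs)]
    pairs = list(zip(genes_a, genes_b))
    na = int(round(f_mf_a * n_pairs))
    nb = int(round(f_mf_b * n_pairs))
    if excess <= 1.0:
        mf_a = frozenset(rng.choice(genes_a, size=na, replace=False).tolist())
        mf_b = frozenset(rng.choice(genes_b, size=nb, replace=False).tolist())
    else:
        q = int(round(excess * n_pairs * f_mf_a * f_mf_b))
        if q > min(na, nb):
            raise ValueError("requested excess exceeds available labels")
        if (na - q) + (nb - q) > n_pairs - q:
            raise ValueError("labels do not fit without extra coincident pairs")
        idx = rng.permutation(n_pairs)
        both = idx[:q]
        rest = idx[q:]
        only_a = rest[: na - q]
        only_b = rest[na - q: (na - q) + (nb - q)]
        mf_a = frozenset(genes_a[i] for i in np.concatenate([both, only_a]))
        mf_b = frozenset(genes_b[i] for i in np.concatenate([both, only_b]))
    truth = SyntheticTruth(
        planted_ortholog_excess=excess,
        parameters={"n_pairs": n_pairs, "f_mf_a": f_mf_a, "f_mf_b": f_mf_b},
        seed=seed,
    )
    return pairs, mf_a, mf_b, truth


# ---------------------------------------------------------------------------
# features


def gen_features(
    genes: Sequence[str],
    group_labels: Mapping[str, str],
    effect_sizes: Mapping[str, float],
    seed: int = 0,
    shifted_group: str | None = None,
) -> pd.DataFrame:
    """Per-gene feature table with planted location shifts.

    Each feature is standard normal noise plus ``effect_sizes[feature]``
    for genes of the shifted group (by default the lexicographically first
    group label).
    """
    rng = np.random.default_rng(seed)
    genes = sorted(genes)
    labels = sorted({group_labels[g] for g in genes})
    if shifted_group is None:
        shifted_group = labels[0]
    shift_mask = np.array([group_labels[g] == shifted_group for g in genes], dtype=float)
    data = {}
    for feat in sorted(effect_sizes):
        data[feat] = rng.normal(size=len(genes)) + effect_sizes[feat] * shift_mask
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    df["group"] = [group_labels[g] for g in genes]
    return df


# ---------------------------------------------------------------------------
# serialization (same dialects the loaders read)


def write_obo(graph: OntologyGraph, stream: IO[str]) -> None:
    stream.write("format-version: 1.2\nontology: synthetic\n\n")
    for tid in sorted(graph.terms):
        term = graph.terms[tid]
        stream.write("[Term]\n")
        stream.write(f"id: {term.id}\n")
        stream.write(f"name: {term.name or term.id}\n")
        if term.namespace:
            stream.write(f"namespace: {term.namespace}\n")
        if term.obsolete:
            stream.write("is_obsolete: true\n")
        else:
            for _, parent, data in graph.graph.out_edges(tid, data=True):
                rel = data.get("relation", "is_a")
                if rel == "is_a":
                    stream.write(f"is_a: {parent}\n")
                else:
                    stream.write(f"relationship: {rel} {parent}\n")
        stream.write("\n")


def write_annotations_tsv(records: Sequence[AnnotationRecord], stream: IO[str]) -> None:
    for rec in sorted(records, key=lambda r: (r.gene, r.term)):
        stream.write(f"{rec.gene}\t{rec.term}\n")


def write_gaf(records: Sequence[AnnotationRecord], stream: IO[str]) -> None:
    stream.write("!gaf-version: 2.1\n")
    for rec in sorted(records, key=lambda r: (r.gene, r.term)):
        fields = [
            "SYN", rec.gene, rec.gene, "|".join(rec.qualifiers), rec.term,
            "SYN:0000", rec.evidence, "", rec.aspect or "P", "", "",
            "gene", "taxon:0", "20130712", "SYN", "", "",
        ]
        stream.write("\t".join(fields) + "\n")


def write_edges(net: InteractionNetwork, stream: IO[str]) -> None:
    for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
        stream.write(f"{a}\t{b}\n")


def write_clusters(clusters: Mapping[str, object], stream: IO[str]) -> None:
    for gene in sorted(clusters):
        stream.write(f"{gene}\t{clusters[gene]}\n")


def write_pairs(pairs: Sequence[tuple[str, str]], stream: IO[str]) -> None:
    for a, b in pairs:
        stream.write(f"{a}\t{b}\n")


def write_gene_set(genes, stream: IO[str]) -> None:
    for g in sorted(genes):
        stream.write(f"{g}\n")
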
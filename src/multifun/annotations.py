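"""GAF parsing, evidence/qualifier filtering, and true-path propagation.

The counting substrate for multifunctionality detection is a
:class:`GeneTermIndex`: gene<->term maps closed under the true-path rule
(an annotation to a term implies annotation to all of its ancestors), so
the gene count of a term is always >= the count of any of its descendants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

from Bio.UniProt.GOA import gafiterator

from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

#: Evidence codes used for the main analysis: all experimental, curated and
#: sequence-based codes, but not electronic (IEA) annotations.
DEFAULT_EVIDENCE = frozenset(
    {
        "EXP", "IDA", "IMP", "IGI", "IEP",
        "ISS", "ISO", "ISA", "ISM", "IGC", "IBA",
        "IC", "TAS", "NAS",
    }
)

#: The most reliable subset: direct experimental evidence and curator/author
#: statements only.
STRICT_EVIDENCE = frozenset({"EXP", "IDA", "IMP", "IEP", "IC", "TAS"})

_ASPECT_TO_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}


@dataclass(frozen=True)
class AnnotationRecord:
    gene: str
    term: str
    evidence: str
    qualifiers: tuple[str, ...] = ()
    aspect: str = ""


@dataclass
class GeneTermIndex:
    """True-path-propagated gene<->term maps.

    Invariant: if ``g`` is counted at term ``t`` it is counted at every
    ancestor of ``t``; the namespace root therefore counts the whole
    universe.
    """

    term_to_genes: dict[str, frozenset[str]]
    gene_to_terms: dict[str, frozenset[str]]
    universe: frozenset[str]
    namespace: str = ""

    def genes(self, term: str) -> frozenset[str]:
        return self.term_to_genes.get(term, frozenset())

    def count(self, term: str) -> int:
        return len(self.term_to_genes.get(term, ()))


def load_gaf(
    stream: IO[str],
    evidence_whitelist: Iterable[str] = DEFAULT_EVIDENCE,
) -> list[AnnotationRecord]:
    """Read a GAF 2.x file into filtered annotation records.

    Records with evidence outside the whitelist or carrying the ``NOT``
    qualifier are removed; duplicates (same gene, same term) are collapsed
    later by set semantics in :func:`build_index`.  Malformed lines are
    skipped with a warning.
    """
    whitelist = frozenset(evidence_whitelist)
    if not whitelist:
        raise ValueError("evidence whitelist must be non-empty")
    records: list[AnnotationRecord] = []
    for rec in gafiterator(stream):
        try:
            gene = rec["DB_Object_ID"]
            term = rec["GO_ID"]
            evidence = rec["Evidence"]
            qualifiers = tuple(q for q in rec.get("Qualifier", []) if q)
            aspect = rec.get("Aspect", "")
        except (KeyError, TypeError):  # pragma: no cover - defensive
            logger.warning("skipping malformed GAF record: %r", rec)
            continue
        if not gene or not term or not evidence:
            logger.warning("skipping incomplete GAF record: %r", rec)
            continue
        if evidence not in whitelist:
            continue
        if any(q == "NOT" or q.startswith("NOT|") or q.endswith("|NOT") for q in qualifiers):
            continue
        records.append(
            AnnotationRecord(gene=gene, term=term, evidence=evidence,
                             qualifiers=qualifiers, aspect=aspect)
        )
    if not records:
        raise ValueError("no annotation records survived filtering")
    return records


def load_gene_term_tsv(stream: IO[str], evidence: str = "EXP") -> list[AnnotationRecord]:
    """Read the plain two-column ``gene<TAB>term`` dialect used by fixtures."""
    records = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            logger.warning("line %d: malformed gene-term row %r, skipped", lineno, line)
            continue
        records.append(AnnotationRecord(gene=parts[0], term=parts[1], evidence=evidence))
    if not records:
        raise ValueError("no annotation records in stream")
    return records


def build_index(
    records: Iterable[AnnotationRecord],
    graph: OntologyGraph,
    namespace: str | None = None,
    propagate: bool = True,
) -> GeneTermIndex:
    """Build the propagated gene<->term index for one namespace.

    Annotations to terms missing from the graph (or obsolete) are skipped
    with a warning.  ``propagate=False`` gives direct-only counts for
    sensitivity analysis; the default true-path counts are what the term
    selection logic assumes.
    """
    gene_to_terms: dict[str, set[str]] = {}
    n_skipped = 0
    for rec in records:
        if namespace is not None:
            rec_ns = _ASPECT_TO_NAMESPACE.get(rec.aspect, rec.aspect)
            if rec_ns and rec_ns != namespace:
                continue
        if rec.term not in graph.terms or graph.terms[rec.term].obsolete:
            n_skipped += 1
            continue
        if namespace is not None and graph.terms[rec.term].namespace not in ("", namespace):
            continue
        terms = gene_to_terms.setdefault(rec.gene, set())
        terms.add(rec.term)
        if propagate:
            terms.update(graph.ancestors(rec.term))
    if n_skipped:
        logger.warning("skipped %d annotations to unknown or obsolete terms", n_skipped)
    if not gene_to_terms:
        raise ValueError("no annotations remain after namespace filtering")

    term_to_genes: dict[str, set[str]] = {}
    for gene, terms in gene_to_terms.items():
        for t in terms:
            term_to_genes.setdefault(t, set()).add(gene)

    return GeneTermIndex(
        term_to_genes={t: frozenset(g) for t, g in term_to_genes.items()},
        gene_to_terms={g: frozenset(t) for g, t in gene_to_terms.items()},
        universe=frozenset(gene_to_terms),
        namespace=namespace or "",
    )
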
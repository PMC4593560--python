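"""Per-gene scalar features derived from raw per-isoform / per-residue /
per-condition inputs.

These are the measured quantities compared between multifunctional and
other annotated genes: protein length (longest isoform), unique domain
family count, intrinsic disorder fraction (share of residues with
predicted disorder score above 0.5), exon conservation (per-isoform mean,
then averaged over isoforms with equal weight), expression breadth,
condition-specific essentiality counts, and multi-disease status from a
disease ontology.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .ontology import OntologyGraph

DISORDER_THRESHOLD = 0.5
CONDITION_P_THRESHOLD = 0.01


def longest_isoform_length(isoform_lengths: Mapping[str, Sequence[int]]) -> dict[str, int]:
    """Length of the longest protein isoform per gene."""
    out = {}
    for gene, lengths in isoform_lengths.items():
        if not lengths:
            raise ValueError(f"gene {gene!r} has no isoforms")
        out[gene] = max(lengths)
    return out


def unique_domain_count(domains: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Number of distinct domain families; repeated instances are ignored."""
    return {gene: len(set(fams)) for gene, fams in domains.items()}


def disorder_fraction(scores: Sequence[float], threshold: float = DISORDER_THRESHOLD) -> float:
    """Fraction of residues with disorder score strictly above the threshold."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty score vector")
    return float(np.mean(arr > threshold))


def conservation_score(per_isoform_scores: Sequence[Sequence[float]]) -> float:
    """Mean conservation per isoform, then averaged over isoforms.

    Isoforms are weighted equally regardless of length.
    """
    if not per_isoform_scores:
        raise ValueError("no isoforms")
    means = [float(np.mean(np.asarray(s, dtype=float))) for s in per_isoform_scores]
    return float(np.mean(means))


def expression_breadth(
    matrix: Mapping[str, Mapping[str, float]],
    rule: str = "nonzero",
    replicates: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, int]:
    """Number of conditions in which a gene is expressed.

    ``rule="nonzero"``: a gene is present in a condition if its value is
    non-zero (e.g. RPKM).  ``rule="all_replicates_present"``: conditions
    group replicate columns (via ``replicates``: condition -> columns) and
    a gene counts as present only when present (non-zero) in every
    replicate of the condition.
    """
    out: dict[str, int] = {}
    if rule == "nonzero":
        for gene, row in matrix.items():
            out[gene] = sum(1 for v in row.values() if v != 0)
    elif rule == "all_replicates_present":
        if replicates is None:
            raise ValueError("all_replicates_present rule needs a replicate map")
        for gene, row in matrix.items():
            n = 0
            for cond, cols in replicates.items():
                if cols and all(row.get(c, 0) != 0 for c in cols):
                    n += 1
            out[gene] = n
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return out


def condition_essentiality_count(
    per_condition_pvalues: Mapping[str, Sequence[float]],
    threshold: float = CONDITION_P_THRESHOLD,
) -> dict[str, int]:
    """Conditions where a deletion strain shows a significant fitness defect."""
    return {
        gene: int(sum(1 for p in ps if p < threshold))
        for gene, ps in per_condition_pvalues.items()
    }


def multi_disease_genes(
    disease_graph: OntologyGraph,
    gene_to_terms: Mapping[str, Iterable[str]],
    root: str,
    full_criterion: bool = False,
) -> frozenset[str]:
    """Genes associated with at least two distinct diseases.

    A gene qualifies when some pair of its disease-ontology terms has only
    the root in common among ancestors (neither term ancestral to the
    other).  By default the shared-descendant clause of term disjointness
    is not applied — two disease terms are distinct diseases when their
    only common ancestor is the root; ``full_criterion=True`` additionally
    requires no common descendant.
    """
    hits = []
    for gene, terms in gene_to_terms.items():
        terms = sorted(set(terms))
        found = False
        for i in range(len(terms)):
            for j in range(i + 1, len(terms)):
                t1, t2 = terms[i], terms[j]
                if full_criterion:
                    ok = disease_graph.is_disjoint_pair(t1, t2, root)
                else:
                    a1 = disease_graph.ancestors(t1)
                    a2 = disease_graph.ancestors(t2)
                    ok = (
                        t1 not in a2
                        and t2 not in a1
                        and not ((a1 & a2) - {root})
                    )
                if ok:
                    found = True
                    break
            if found:
                break
        if found:
            hits.append(gene)
    return frozenset(hits)
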
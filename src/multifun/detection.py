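"""Multifunctional-gene detection.

A gene is called multifunctional when it is co-annotated by two terms of
comparable specificity that are sufficiently distinct.  The procedure:

1. For a specificity threshold ``N``, select the term set ``T_N`` of all
   terms annotating at least ``N`` but fewer than ``2N`` genes whose every
   descendant annotates fewer than ``N`` genes (terms with no descendants
   qualify vacuously).  This refines the classic "informative terms"
   selection, which would accept very general terms whose children are all
   small.
2. From all unordered pairs of terms in ``T_N``, keep those that (a) share
   no common ancestor other than the namespace root, share no common
   descendant, and have no ancestor/descendant relation with each other,
   and (b) do not co-annotate significantly overlapping gene sets
   (one-sided hypergeometric test on the overlap, raw ``p >= alpha``).
3. Every gene co-annotated by at least one passing pair at at least one
   level is multifunctional.  Levels run over ``N = 10, 20, ..., M``; the
   final call set is the union over levels.

The background for downstream comparisons is the set of genes annotated by
any selected term at any level; "other annotated genes" are the background
minus the multifunctional set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from scipy.stats import hypergeom

from .annotations import GeneTermIndex
from .ontology import OntologyGraph

DEFAULT_MAX_SPECIFICITY = 120
DEFAULT_INCREMENT = 10
DEFAULT_ALPHA = 0.1
DEFAULT_MIN_SPECIFICITY = 10


@dataclass(frozen=True)
class EvidencePair:
    """One witness of a gene's multifunctionality."""

    N: int
    term1: str
    term2: str
    overlap: int
    pvalue: float


@dataclass
class SpecificityLevel:
    """Selected terms and filter-passing pairs at one threshold ``N``."""

    N: int
    selected_terms: frozenset[str]
    passing_pairs: frozenset[tuple[str, str]]  # pairs stored sorted


@dataclass
class MultifunctionalityResult:
    multifunctional: frozenset[str]
    background: frozenset[str]
    evidence: dict[str, list[EvidencePair]]
    levels: list[SpecificityLevel]
    parameters: dict = field(default_factory=dict)

    @property
    def other_annotated(self) -> frozenset[str]:
        return self.background - self.multifunctional


def select_terms(index: GeneTermIndex, graph: OntologyGraph, N: int) -> frozenset[str]:
    """The specificity-level term set ``T_N``.

    ``T_N = {t : N <= count(t) < 2N and every descendant of t counts < N}``
    with true-path-propagated counts.  The root gets no special treatment:
    it is excluded automatically whenever its count is >= 2N.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not index.term_to_genes:
        raise ValueError("empty annotation index")
    selected = []
    for term, genes in index.term_to_genes.items():
        c = len(genes)
        if not (N <= c < 2 * N):
            continue
        if any(index.count(d) >= N for d in graph.descendants(term)):
            continue
        selected.append(term)
    return frozenset(selected)


def coannotation_pvalue(k: int, a: int, b: int, G: int) -> float:
    """Upper-tail hypergeometric probability of a co-annotation overlap.

    Probability that two random gene sets of sizes ``a`` and ``b`` drawn
    from a universe of ``G`` genes share at least ``k`` genes; symmetric in
    ``(a, b)``.
    """
    if not (0 <= k <= min(a, b) and 0 <= a <= G and 0 <= b <= G):
        raise ValueError(f"inconsistent counts k={k}, a={a}, b={b}, G={G}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, G, a, b))


def filter_pairs(
    level_terms: frozenset[str],
    graph: OntologyGraph,
    index: GeneTermIndex,
    root: str,
    alpha: float = DEFAULT_ALPHA,
) -> frozenset[tuple[str, str]]:
    """Distinct-pair filtering within one specificity level.

    A pair survives iff it is disjoint in the root-only-LCA sense (no shared
    non-root ancestor, no shared descendant, no mutual ancestry) and its
    gene-set overlap is not larger than chance expects (hypergeometric
    ``p >= alpha``).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    G = len(index.universe)
    passing = []
    for t1, t2 in itertools.combinations(sorted(level_terms), 2):
        if not graph.is_disjoint_pair(t1, t2, root):
            continue
        g1, g2 = index.genes(t1), index.genes(t2)
        p = coannotation_pvalue(len(g1 & g2), len(g1), len(g2), G)
        if p >= alpha:
            passing.append((t1, t2))
    return frozenset(passing)


def detect_multifunctional(
    index: GeneTermIndex,
    graph: OntologyGraph,
    root: str,
    M: int = DEFAULT_MAX_SPECIFICITY,
    increment: int = DEFAULT_INCREMENT,
    alpha: float = DEFAULT_ALPHA,
    min_specificity: int = DEFAULT_MIN_SPECIFICITY,
) -> MultifunctionalityResult:
    """Run the full multi-level detection and return calls with evidence.

    Evidence records every ``(N, term1, term2)`` pair witnessing each call,
    with the pair's overlap and hypergeometric p-value.  Output ordering is
    deterministic (genes lexicographic; evidence by ``(N, term1, term2)``)
    so repeated runs are byte-identical.
    """
    if M < min_specificity:
        raise ValueError(f"M must be >= {min_specificity}")
    if increment < 1:
        raise ValueError("increment must be >= 1")
    G = len(index.universe)

    levels: list[SpecificityLevel] = []
    evidence: dict[str, list[EvidencePair]] = {}
    background: set[str] = set()
    any_selected = False
    for N in range(min_specificity, M + 1, increment):
        terms = select_terms(index, graph, N)
        pairs = filter_pairs(terms, graph, index, root, alpha)
        levels.append(SpecificityLevel(N=N, selected_terms=terms, passing_pairs=pairs))
        any_selected = any_selected or bool(terms)
        for t in terms:
            background |= index.genes(t)
        for t1, t2 in sorted(pairs):
            g1, g2 = index.genes(t1), index.genes(t2)
            shared = g1 & g2
            if not shared:
                continue
            p = coannotation_pvalue(len(shared), len(g1), len(g2), G)
            ev = EvidencePair(N=N, term1=t1, term2=t2, overlap=len(shared), pvalue=p)
            for gene in shared:
                evidence.setdefault(gene, []).append(ev)

    if not any_selected:
        counts = sorted((len(g) for g in index.term_to_genes.values()), reverse=True)
        raise ValueError(
            "no specificity level selected any term; "
            f"top term counts: {counts[:10]} (universe {G}, grid "
            f"{min_specificity}..{M} step {increment})"
        )

    for gene in evidence:
        evidence[gene].sort(key=lambda e: (e.N, e.term1, e.term2))
    multifunctional = frozenset(evidence)
    return MultifunctionalityResult(
        multifunctional=multifunctional,
        background=frozenset(background),
        evidence={g: evidence[g] for g in sorted(evidence)},
        levels=levels,
        parameters={
            "M": M,
            "increment": increment,
            "alpha": alpha,
            "min_specificity": min_specificity,
            "root": root,
            "universe_size": G,
        },
    )
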
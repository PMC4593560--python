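from fractions import Fraction
import itertools

import numpy as np
import pytest

from multifun.annotations import build_index
from multifun.detection import (
    coannotation_pvalue,
    detect_multifunctional,
    filter_pairs,
    select_terms,
)
from multifun.synthetic import gen_annotations, gen_ontology

from brute_force import hypergeom_tail
from conftest import make_graph, records_from


def _index_with_counts(counts: dict[str, int], graph):
    """Annotate distinct genes directly to each term to force exact counts.

    Only meaningful when the terms are leaves or when parent counts are
    given explicitly as supersets; used for select_terms unit cases where
    we drive counts through disjoint leaf populations.
    """
    gene_terms = {}
    i = 0
    for term, n in counts.items():
        for _ in range(n):
            gene_terms[f"g{i}"] = {term}
            i += 1
    return build_index(records_from(gene_terms), graph)


class TestSelectTerms:
    def test_term_selected_when_descendants_below_n(self):
        # term B has 100 genes (60 direct + 40 via child C); child C has 40 < 90
        g = make_graph([("B", "A"), ("C", "B")])
        idx = _index_with_counts({"B": 60, "C": 40}, g)
        assert idx.count("B") == 100
        selected = select_terms(idx, g, N=90)
        assert "B" in selected
        assert "C" not in selected  # count 40 < N

    def test_general_term_with_small_descendants_rejected_by_2n_bound(self):
        # a term annotating 508 genes whose descendants each stay below 82
        # is never selected anywhere on the 10..120 grid: 508 >= 2N for all N
        g = make_graph([("W", "A"), ("D1", "W"), ("D2", "W")])
        idx = _index_with_counts({"W": 344, "D1": 82, "D2": 82}, g)
        assert idx.count("W") == 508
        for n in range(10, 121, 10):
            assert "W" not in select_terms(idx, g, n)

    def test_leaf_with_count_exactly_n_selected(self):
        g = make_graph([("B", "A")])
        idx = _index_with_counts({"B": 10}, g)
        assert "B" in select_terms(idx, g, N=10)
        assert "B" not in select_terms(idx, g, N=11)

    def test_descendant_at_n_blocks_parent(self):
        g = make_graph([("B", "A"), ("C", "B")])
        idx = _index_with_counts({"B": 5, "C": 90}, g)  # B propagates to 95
        assert "B" not in select_terms(idx, g, N=90)

    def test_empty_index_is_error(self, chain):
        idx = build_index(records_from({"g": {"C"}}), chain)
        idx.term_to_genes = {}
        with pytest.raises(ValueError):
            select_terms(idx, chain, N=10)


class TestCoannotationPvalue:
    def test_zero_overlap_is_one(self):
        assert coannotation_pvalue(0, 10, 10, 100) == 1.0

    def test_small_universe_enumeration(self):
        # G=4, a=2, b=2, k=2: only one of the C(4,2)=6 draws overlaps fully
        assert coannotation_pvalue(2, 2, 2, 4) == pytest.approx(1 / 6, abs=1e-15)

    def test_matches_exact_rational_tail(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            G = int(rng.integers(2, 13))
            a = int(rng.integers(1, G + 1))
            b = int(rng.integers(1, G + 1))
            k = int(rng.integers(0, min(a, b) + 1))
            assert coannotation_pvalue(k, a, b, G) == pytest.approx(
                float(hypergeom_tail(k, a, b, G)), abs=1e-12
            )

    def test_symmetric_in_a_b(self):
        assert coannotation_pvalue(3, 7, 11, 40) == pytest.approx(
            coannotation_pvalue(3, 11, 7, 40), abs=1e-15
        )

    def test_significant_overlap_below_alpha(self):
        assert coannotation_pvalue(5, 10, 10, 100) < 0.1

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            coannotation_pvalue(5, 3, 10, 100)


@pytest.fixture
def two_branch_fixture():
    """Root A, branches B1/B2 with leaves L1/L2; D is a shared child of X1, X2."""
    g = make_graph(
        [("B1", "A"), ("B2", "A"), ("L1", "B1"), ("L2", "B2"),
         ("X1", "A"), ("X2", "A"), ("D", "X1"), ("D", "X2")]
    )
    gene_terms = {}
    for i in range(12):
        gene_terms[f"p{i}"] = {"L1"}
    for i in range(12):
        gene_terms[f"q{i}"] = {"L2"}
    for i in range(12):
        gene_terms[f"r{i}"] = {"D"}
    idx = build_index(records_from(gene_terms), g)
    return g, idx


class TestFilterPairs:
    def test_disjoint_pair_with_zero_overlap_retained(self, two_branch_fixture):
        g, idx = two_branch_fixture
        pairs = filter_pairs(frozenset({"L1", "L2"}), g, idx, "A", alpha=0.1)
        assert pairs == {("L1", "L2")}

    def test_common_descendant_pair_removed(self, two_branch_fixture):
        g, idx = two_branch_fixture
        assert filter_pairs(frozenset({"X1", "X2"}), g, idx, "A", alpha=0.1) == frozenset()

    def test_enriched_overlap_removed(self):
        g = make_graph([("B1", "A"), ("B2", "A")])
        gene_terms = {f"s{i}": {"B1", "B2"} for i in range(5)}
        gene_terms.update({f"t{i}": {"B1"} for i in range(5)})
        gene_terms.update({f"u{i}": {"B2"} for i in range(5)})
        gene_terms.update({f"v{i}": {"A"} for i in range(85)})
        idx = build_index(records_from(gene_terms), g)
        assert idx.count("B1") == idx.count("B2") == 10
        assert len(idx.universe) == 100
        assert filter_pairs(frozenset({"B1", "B2"}), g, idx, "A", alpha=0.1) == frozenset()


class TestDetect:
    def test_gene_coannotated_by_passing_pair_called(self, two_branch_fixture):
        g, idx = two_branch_fixture
        # add one gene on both branches at matching counts
        gene_terms = {f"p{i}": {"L1"} for i in range(12)}
        gene_terms.update({f"q{i}": {"L2"} for i in range(12)})
        gene_terms["mf"] = {"L1", "L2"}
        idx = build_index(records_from(gene_terms), g)
        res = detect_multifunctional(idx, g, "A", M=20, increment=10, alpha=0.1)
        assert res.multifunctional == {"mf"}
        assert all(e.N in (10, 20) for e in res.evidence["mf"])

    def test_single_term_gene_in_background_only(self, two_branch_fixture):
        g, idx = two_branch_fixture
        res = detect_multifunctional(idx, g, "A", M=20, increment=10, alpha=0.1)
        assert res.multifunctional == frozenset()
        assert "p0" in res.background

    def test_no_selected_terms_raises_with_diagnostic(self, two_branch_fixture):
        g, idx = two_branch_fixture
        with pytest.raises(ValueError, match="top term counts"):
            detect_multifunctional(idx, g, "A", M=10, increment=10, alpha=0.1,
                                   min_specificity=5)  # counts 12..36 vs window [5,10)

    def test_level_union_monotone_in_m(self):
        graph = gen_ontology(seed=5)
        records, _ = gen_annotations(graph, seed=5)
        idx = build_index(records, graph)
        root = sorted(graph.roots())[0]
        prev_mf, prev_bg = frozenset(), frozenset()
        for M in (10, 30, 60, 120):
            res = detect_multifunctional(idx, graph, root, M=M)
            assert prev_mf <= res.multifunctional
            assert prev_bg <= res.background
            prev_mf, prev_bg = res.multifunctional, res.background

    def test_alpha_monotonicity(self):
        graph = gen_ontology(seed=6)
        records, _ = gen_annotations(graph, coannotation_enrichment=3.0, seed=6)
        idx = build_index(records, graph)
        root = sorted(graph.roots())[0]
        prev = None
        for alpha in (0.5, 0.2, 0.1, 0.01):
            res = detect_multifunctional(idx, graph, root, alpha=alpha)
            if prev is not None:
                # lowering alpha keeps more pairs, never removes calls
                assert prev <= res.multifunctional
            prev = res.multifunctional

    def test_evidence_pairs_recheck_against_filters(self):
        graph = gen_ontology(seed=7)
        records, _ = gen_annotations(graph, coannotation_enrichment=3.0, seed=7)
        idx = build_index(records, graph)
        root = sorted(graph.roots())[0]
        res = detect_multifunctional(idx, graph, root)
        G = len(idx.universe)
        for gene, evs in res.evidence.items():
            for e in evs:
                level = next(l for l in res.levels if l.N == e.N)
                assert e.term1 in level.selected_terms
                assert e.term2 in level.selected_terms
                assert graph.is_disjoint_pair(e.term1, e.term2, root)
                p = hypergeom_tail(
                    len(idx.genes(e.term1) & idx.genes(e.term2)),
                    idx.count(e.term1), idx.count(e.term2), G,
                )
                assert p >= Fraction(1, 10)
                assert gene in idx.genes(e.term1) & idx.genes(e.term2)

    def test_deterministic_evidence_ordering(self):
        graph = gen_ontology(seed=8)
        records, _ = gen_annotations(graph, seed=8)
        idx = build_index(records, graph)
        root = sorted(graph.roots())[0]
        r1 = detect_multifunctional(idx, graph, root)
        r2 = detect_multifunctional(idx, graph, root)
        assert list(r1.evidence) == sorted(r1.evidence)
        assert r1.evidence == r2.evidence
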
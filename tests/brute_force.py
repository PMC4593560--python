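"""Independent brute-force oracles for the test suite.

Everything here re-derives results literally from first principles:
reachability by plain DFS over explicit edge lists, hypergeometric tails
as exact rational sums of binomial terms, and the full multifunctionality
pipeline as a direct transcription of its definitions.  Nothing imports
the implementation's algorithms; the package's data containers are used
only as passive inputs.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def closure_maps(edges: list[tuple[str, str]], nodes: list[str]):
    """Ancestor/descendant sets by DFS over an explicit child->parent edge list."""
    parents: dict[str, set[str]] = {n: set() for n in nodes}
    children: dict[str, set[str]] = {n: set() for n in nodes}
    for child, parent in edges:
        parents[child].add(parent)
        children[parent].add(child)

    def reach(start: str, step: dict[str, set[str]]) -> frozenset[str]:
        seen: set[str] = set()
        stack = list(step[start])
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            stack.extend(step[n])
        return frozenset(seen)

    anc = {n: reach(n, parents) for n in nodes}
    desc = {n: reach(n, children) for n in nodes}
    return anc, desc


def hypergeom_tail(k: int, a: int, b: int, G: int) -> Fraction:
    """Exact rational upper tail P[X >= k] for overlap of an a-set and b-draw."""
    total = comb(G, b)
    num = sum(comb(a, i) * comb(G - a, b - i)
              for i in range(k, min(a, b) + 1) if b - i <= G - a)
    return Fraction(num, total)


def brute_pipeline(
    gene_annotations: dict[str, set[str]],
    edges: list[tuple[str, str]],
    terms: list[str],
    root: str,
    M: int = 120,
    increment: int = 10,
    alpha: Fraction = Fraction(1, 10),
    min_n: int = 10,
):
    """Literal multifunctionality pipeline from the definitions.

    ``gene_annotations`` maps genes to their *directly* annotated terms;
    propagation, T_N selection, the three pair filters and the union over
    levels are all recomputed here from scratch.

    Returns (multifunctional, background, evidence) where evidence is the
    set of (gene, N, t1, t2) witnesses.
    """
    anc, desc = closure_maps(edges, terms)

    # true-path propagation
    gene_terms = {
        g: set().union(*({t} | anc[t] for t in ts))
        for g, ts in gene_annotations.items()
    }
    term_genes: dict[str, set[str]] = {t: set() for t in terms}
    for g, ts in gene_terms.items():
        for t in ts:
            term_genes[t].add(g)
    universe = set(gene_terms)
    G = len(universe)

    multifunctional: set[str] = set()
    background: set[str] = set()
    evidence: set[tuple[str, int, str, str]] = set()
    any_level = False
    for N in range(min_n, M + 1, increment):
        t_n = [
            t for t in terms
            if N <= len(term_genes[t]) < 2 * N
            and all(len(term_genes[d]) < N for d in desc[t])
        ]
        any_level = any_level or bool(t_n)
        for t in t_n:
            background |= term_genes[t]
        for t1, t2 in itertools.combinations(sorted(t_n), 2):
            if t1 in anc[t2] or t2 in anc[t1]:
                continue
            if (anc[t1] & anc[t2]) - {root}:
                continue
            if desc[t1] & desc[t2]:
                continue
            shared = term_genes[t1] & term_genes[t2]
            p = hypergeom_tail(len(shared), len(term_genes[t1]), len(term_genes[t2]), G)
            if p < alpha:
                continue
            for g in shared:
                multifunctional.add(g)
                evidence.add((g, N, t1, t2))
    if not any_level:
        raise ValueError("no level selected any term")
    return multifunctional, background, evidence


def brute_betweenness(adj: dict[str, set[str]]) -> dict[str, float]:
    """Betweenness by explicit enumeration of all shortest paths (tiny graphs)."""
    nodes = sorted(adj)
    score = {n: 0.0 for n in nodes}

    def all_shortest_paths(s: str, t: str) -> list[list[str]]:
        # BFS layers, then enumerate paths following decreasing distance-to-s
        dist = {s: 0}
        frontier = [s]
        while frontier and t not in dist:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if t not in dist:
            return []
        paths: list[list[str]] = []

        def extend(path: list[str]) -> None:
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in adj[u]:
                if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                    path.append(v)
                    extend(path)
                    path.pop()

        extend([s])
        return paths

    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            w = 1.0 / len(paths)
            for path in paths:
                for v in path[1:-1]:
                    score[v] += w
    return score


def mann_whitney_exact_enumeration(a: list[float], b: list[float]) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group labelings."""
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"
    n1 = len(a)

    def u_stat(sample_a: tuple[float, ...]) -> float:
        rest = list(pooled)
        for x in sample_a:
            rest.remove(x)
        return sum(1 for x in sample_a for y in rest if x > y)

    observed = u_stat(tuple(a))
    mu = n1 * (len(pooled) - n1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(pooled, n1):
        u = u_stat(combo)
        total += 1
        if abs(u - mu) >= abs(observed - mu):
            count += 1
    return count / total
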
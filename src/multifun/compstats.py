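"""Group-comparison and bias-control statistics.

Mann-Whitney U comparisons between multifunctional and other annotated
genes, hypergeometric set enrichment, (partial) Spearman correlation,
stratified comparison, covariate-matched resampling null models, and
bootstrap confidence intervals for medians.  All stochastic procedures
take explicit seeds and empirical p-values follow the ``(r + 1)/(n + 1)``
convention, so 1000 trials with zero exceedances report p < 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detection import coannotation_pvalue

EXACT_MW_LIMIT = 400  # n1*n2 at or below this: exact enumeration (no ties)


@dataclass
class ComparisonResult:
    n1: int
    n2: int
    mean1: float
    mean2: float
    median1: float
    median2: float
    U: float
    pvalue: float
    direction: str  # "group1", "group2" or "none"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class MatchedNullResult:
    observed: float
    null_samples: np.ndarray
    pvalue: float
    ci_low: float
    ci_high: float
    n_trials: int
    seed: int
    binning: str


def mann_whitney(a, b) -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison of two samples.

    Uses exact enumeration when ``n1 * n2 <= 400`` and the pooled sample is
    tie-free; otherwise the tie- and continuity-corrected normal
    approximation (identical samples give exactly p = 1 on both paths).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size * b.size <= EXACT_MW_LIMIT and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    med1, med2 = float(np.median(a)), float(np.median(b))
    mu = a.size * b.size / 2.0
    if res.statistic > mu:
        direction = "group1"
    elif res.statistic < mu:
        direction = "group2"
    else:
        direction = "none"
    return ComparisonResult(
        n1=int(a.size), n2=int(b.size),
        mean1=float(a.mean()), mean2=float(b.mean()),
        median1=med1, median2=med2,
        U=float(res.statistic), pvalue=float(min(res.pvalue, 1.0)),
        direction=direction,
    )


def enrichment(hits_in_set: int, set_size: int, hits_total: int, background: int) -> float:
    """Upper-tail hypergeometric enrichment of hits in a gene set.

    Probability of observing at least ``hits_in_set`` hits when drawing
    ``set_size`` genes from a background of ``background`` genes containing
    ``hits_total`` hits.  Shares the implementation of the co-annotation
    filter.
    """
    if hits_in_set > min(set_size, hits_total):
        raise ValueError("hits_in_set exceeds set_size or hits_total")
    return coannotation_pvalue(hits_in_set, hits_total, set_size, background)


def _check_corr_inputs(*vecs) -> list[np.ndarray]:
    arrs = [np.asarray(v, dtype=float) for v in vecs]
    n = arrs[0].size
    if any(a.size != n for a in arrs) or n < 3:
        raise ValueError("inputs must have equal length >= 3")
    for a in arrs:
        if np.unique(a).size == 1:
            raise ValueError("constant vector: rank correlation undefined")
    return arrs


def spearman(x, y) -> float:
    x, y = _check_corr_inputs(x, y)
    return float(stats.spearmanr(x, y).statistic)


def partial_spearman(x, y, control) -> float:
    """Spearman correlation of x and y controlling for a third variable.

    Computed as the Pearson correlation of the residuals of the ranks of x
    and y after linear regression on the ranks of the control.
    """
    x, y, control = _check_corr_inputs(x, y, control)
    rx, ry, rc = (stats.rankdata(v) for v in (x, y, control))
    design = np.column_stack([np.ones_like(rc), rc])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    return float(stats.pearsonr(res_x, res_y).statistic)


def stratified_compare(values, groups, strata) -> dict[object, ComparisonResult | None]:
    """Mann-Whitney within each stratum (e.g. per isoform count).

    ``values``, ``groups`` (labels "A"/"B" or any two labels) and ``strata``
    are gene-keyed mappings.  Strata where either group has < 2 genes are
    reported as ``None`` (skipped).
    """
    labels = sorted({groups[g] for g in values if g in groups})
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    out: dict[object, ComparisonResult | None] = {}
    strata_ids = sorted({strata[g] for g in values if g in strata})
    any_valid = False
    for s in strata_ids:
        a = [values[g] for g in values if g in groups and strata.get(g) == s and groups[g] == labels[0]]
        b = [values[g] for g in values if g in groups and strata.get(g) == s and groups[g] == labels[1]]
        if len(a) < 2 or len(b) < 2:
            out[s] = None
            continue
        out[s] = mann_whitney(a, b)
        any_valid = True
    if not any_valid:
        raise ValueError("no stratum has >= 2 genes in both groups")
    return out


def _bin_edges(target_values: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.quantile(target_values, qs)
    return np.unique(edges)


def matched_resample(
    target_genes,
    candidate_genes,
    covariate,
    response,
    n_trials: int = 1000,
    seed: int = 0,
    statistic: str = "median",
    n_bins: int = 10,
    alternative: str = "greater",
) -> MatchedNullResult:
    """Covariate-matched resampling null for a response statistic.

    Draws ``n_trials`` samples of ``len(target_genes)`` candidates whose
    covariate distribution matches the targets' (quantile bins of the
    target distribution; exact-value bins when the covariate takes few
    integer values, as with isoform counts), then compares the observed
    response statistic of the targets against the null distribution.
    Candidates are drawn within bins with replacement, so a single
    candidate per occupied bin suffices.
    """
    target_genes = sorted(target_genes)
    candidate_genes = sorted(candidate_genes)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    tcov = np.array([covariate[g] for g in target_genes], dtype=float)
    ccov = np.array([covariate[g] for g in candidate_genes], dtype=float)

    uniq = np.unique(tcov)
    if uniq.size <= n_bins and np.allclose(uniq, np.round(uniq)):
        binning = f"exact-value ({uniq.size} values)"
        bin_ids = uniq
        t_assign = tcov
        c_assign = ccov
    else:
        edges = _bin_edges(tcov, n_bins)
        binning = f"{edges.size - 1} quantile bins of target covariate"
        inner = edges[1:-1]
        t_assign = np.searchsorted(inner, tcov, side="right")
        c_assign = np.searchsorted(inner, ccov, side="right")
        bin_ids = np.unique(t_assign)

    cand_by_bin: dict[float, np.ndarray] = {}
    counts_by_bin: dict[float, int] = {}
    for b in bin_ids:
        n_t = int(np.sum(t_assign == b))
        if n_t == 0:
            continue
        idx = np.flatnonzero(c_assign == b)
        if idx.size == 0:
            raise ValueError(f"no candidate gene falls in covariate bin {b!r}")
        cand_by_bin[b] = idx
        counts_by_bin[b] = n_t

    resp_t = np.array([response[g] for g in target_genes], dtype=float)
    resp_c = np.array([response[g] for g in candidate_genes], dtype=float)
    stat = _resolve_statistic(statistic)
    observed = stat(resp_t)

    null = np.empty(n_trials)
    for i in range(n_trials):
        draws = [rng.choice(idx, size=counts_by_bin[b], replace=True)
                 for b, idx in cand_by_bin.items()]
        null[i] = stat(resp_c[np.concatenate(draws)])

    pvalue = empirical_pvalue(observed, null, alternative=alternative)
    lo, hi = np.percentile(null, [2.5, 97.5])
    return MatchedNullResult(
        observed=float(observed), null_samples=null, pvalue=pvalue,
        ci_low=float(lo), ci_high=float(hi),
        n_trials=n_trials, seed=seed, binning=binning,
    )


def _resolve_statistic(statistic: str):
    if statistic == "median":
        return np.median
    if statistic == "mean":
        return np.mean
    if statistic == "proportion":
        return np.mean  # binary response: mean is the proportion
    raise ValueError(f"unknown statistic {statistic!r}")


def empirical_pvalue(observed: float, null: np.ndarray, alternative: str = "greater") -> float:
    """Rank-based empirical p-value, (exceedances + 1) / (trials + 1)."""
    null = np.asarray(null, dtype=float)
    if alternative == "greater":
        r = int(np.sum(null >= observed))
    elif alternative == "less":
        r = int(np.sum(null <= observed))
    elif alternative == "two-sided":
        center = float(np.mean(null))
        r = int(np.sum(np.abs(null - center) >= abs(observed - center)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (r + 1) / (null.size + 1)


def bootstrap_median_ci(sample, n_boot: int = 1000, seed: int = 0,
                        level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the median."""
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2:
        raise ValueError("need at least two observations")
    rng = np.random.default_rng(seed)
    meds = np.median(
        rng.choice(sample, size=(n_boot, sample.size), replace=True), axis=1
    )
    tail = (1 - level) / 2 * 100
    lo, hi = np.percentile(meds, [tail, 100 - tail])
    return float(lo), float(hi)
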
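"""Cross-species conservation of multifunctionality.

Given ortholog pairs between two organisms and each organism's
multifunctional gene set, count pairs where both members are
multifunctional and assess significance by permuting the
multifunctional/other labels within each organism over the genes involved
in orthologous relationships, keeping the orthology map fixed.  Families
may be many-to-many; every listed cross-product pair counts (the statistic
counts pairs, not families), and each gene receives exactly one label per
trial even when it appears in several pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable

import numpy as np

from .compstats import empirical_pvalue

logger = logging.getLogger(__name__)


@dataclass
class PermutationTestResult:
    observed: int
    null_mean: float
    null_sd: float
    null_counts: np.ndarray
    pvalue: float
    n_trials: int
    seed: int


def load_pairs(stream: IO[str]) -> list[tuple[str, str]]:
    """Read an ortholog TSV (geneA, geneB[, family_id])."""
    pairs = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            logger.warning("line %d: malformed ortholog row %r, skipped", lineno, line)
            continue
        pairs.append((parts[0], parts[1]))
    if not pairs:
        raise ValueError("no ortholog pairs in stream")
    return pairs


def count_mf_pairs(pairs: Iterable[tuple[str, str]], mf_a: set[str], mf_b: set[str]) -> int:
    """Pairs whose organism-A gene and organism-B gene are both multifunctional."""
    return sum(1 for a, b in pairs if a in mf_a and b in mf_b)


def permutation_test(
    pairs: list[tuple[str, str]],
    mf_a: set[str],
    mf_b: set[str],
    n_trials: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Label-permutation significance test for the both-multifunctional count.

    Per trial the multifunctional labels are shuffled independently within
    each organism over the ortholog-involved genes (label counts
    preserved); the orthology relationships themselves never change.
    Empirical p follows ``(r + 1)/(n + 1)`` with upper-tail exceedances.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    genes_a = sorted({a for a, _ in pairs})
    genes_b = sorted({b for _, b in pairs})
    idx_a = {g: i for i, g in enumerate(genes_a)}
    idx_b = {g: i for i, g in enumerate(genes_b)}
    pa = np.array([idx_a[a] for a, _ in pairs])
    pb = np.array([idx_b[b] for _, b in pairs])

    lab_a = np.array([g in mf_a for g in genes_a])
    lab_b = np.array([g in mf_b for g in genes_b])
    observed = int(np.sum(lab_a[pa] & lab_b[pb]))

    rng = np.random.default_rng(seed)
    null = np.empty(n_trials, dtype=np.int64)
    for i in range(n_trials):
        sa = rng.permutation(lab_a)
        sb = rng.permutation(lab_b)
        null[i] = np.sum(sa[pa] & sb[pb])

    return PermutationTestResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_trials > 1 else 0.0,
        null_counts=null,
        pvalue=empirical_pvalue(observed, null, alternative="greater"),
        n_trials=n_trials,
        seed=seed,
    )
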
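"""Top-fraction enrichment assay with cumulative hypergeometric expectation.

Genes are ranked by a per-gene score, the top fraction (default 20%) is cut,
and each functional category (plus any curated gene set) is tested for
over-representation: fold = (k/n)/(K/N) and E = P(X >= k) under the
hypergeometric null of drawing n genes from N with K category members.
E-values are raw (no multiple-testing correction), matching the assay's
reporting convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .genome_io import CategoryMap, Gene, GeneSet, match_category, match_gene_set

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRow:
    """One category's contingency record for the enrichment table."""

    category: str
    found_k: int
    existing_K: int
    sample_n: int
    population_N: int
    fold: float
    e_value: float


def rank_and_cut(scores: Mapping[int, float], cut_fraction: float) -> list[int]:
    """Top floor(cut_fraction * N) gene indices by descending score.

    Ties are broken by ascending order index (stable and deterministic).
    """
    if not scores:
        raise ValueError("empty score mapping")
    if not 0.0 < cut_fraction <= 1.0:
        raise ValueError("cut_fraction must lie in (0, 1]")
    m = math.floor(cut_fraction * len(scores))
    if m == 0:
        raise ValueError("cut fraction selects zero genes")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [idx for idx, _ in ranked[:m]]


def _log_pmf(N: int, K: int, n: int, k: np.ndarray) -> np.ndarray:
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) of Hypergeometric(N, K, n), via log-gamma.

    The tail includes the observed count (the standard over-representation
    convention).
    """
    if not (0 <= k <= n <= N):
        raise ValueError(f"require 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not 0 <= K <= N:
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    lo = max(k, max(0, n + K - N))
    hi = min(n, K)
    if k <= max(0, n + K - N):
        return 1.0
    if lo > hi:
        return 0.0
    ks = np.arange(lo, hi + 1, dtype=float)
    tail = float(np.exp(logsumexp(_log_pmf(N, K, n, ks))))
    return min(1.0, max(0.0, tail))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n)/(K/N): sample category rate over population rate; 0 when k=0."""
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("n, K and N must be positive")
    if k == 0:
        return 0.0
    return (k / n) / (K / N)


def enrich(
    genes: Sequence[Gene],
    sample_indices: Sequence[int],
    categories: CategoryMap,
    extra_sets: Sequence[GeneSet] = (),
) -> list[EnrichmentRow]:
    """Per-category fold enrichment and expectation for a gene sample.

    The population is always the full CDS gene list, even when the sample
    was pre-filtered (e.g. hypothetical proteins removed from a
    neighborhood sample); categories with zero genome-wide members are
    omitted with a warning. Rows are sorted by descending fold.
    """
    N = len(genes)
    sample = set(sample_indices)
    if not sample <= {g.order_index for g in genes}:
        raise ValueError("sample indices outside the genome")
    n = len(sample)
    if n == 0:
        raise ValueError("empty sample")

    rows: list[EnrichmentRow] = []

    def add_row(name: str, members: set[int]) -> None:
        K = len(members)
        if K == 0:
            log.warning("category %r has no genes in this genome; row omitted", name)
            return
        k = len(members & sample)
        rows.append(
            EnrichmentRow(
                category=name,
                found_k=k,
                existing_K=K,
                sample_n=n,
                population_N=N,
                fold=fold_enrichment(k, n, K, N),
                e_value=hypergeom_tail(N, K, n, k),
            )
        )

    for name, keywords in categories.items():
        add_row(name, match_category(genes, keywords))
    for gset in extra_sets:
        add_row(gset.name, set(match_gene_set(genes, gset)))

    rows.sort(key=lambda r: (-r.fold, r.category))
    return rows
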
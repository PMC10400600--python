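"""Gene-neighborhood sampling: deduplicated windows around a seed gene set.

The genome is treated as a linear sequence of genes in annotation order
(gene-order distance, not base pairs); a ``circular`` flag enables wrap-around
for circular chromosomes, whose effect is at most ``radius`` genes at the
origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .genome_io import Gene, match_category

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NeighborhoodQuery:
    """Window query around a seed gene set.

    ``radius`` is in genes (default 5); genes whose product matches any
    ``exclude_keywords`` entry are dropped from the result (default filters
    hypothetical proteins); seeds themselves are excluded unless
    ``include_seeds``.
    """

    seed_indices: frozenset[int]
    radius: int = 5
    exclude_keywords: tuple[str, ...] = ("hypothetical protein",)
    include_seeds: bool = False
    circular: bool = False

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if not self.seed_indices:
            raise ValueError("seed set is empty")


def neighbor_set(genes: Sequence[Gene], query: NeighborhoodQuery) -> list[int]:
    """Sorted, deduplicated indices within +/- radius of any seed gene."""
    n = len(genes)
    seeds = set(query.seed_indices)
    if not seeds <= set(range(n)):
        raise ValueError("seed indices outside the genome")

    out: set[int] = set()
    for s in seeds:
        if query.circular:
            out.update((s + d) % n for d in range(-query.radius, query.radius + 1))
        else:
            out.update(range(max(0, s - query.radius), min(n, s + query.radius + 1)))
    if not query.include_seeds:
        out -= seeds
    if query.exclude_keywords:
        excluded = {
            g.order_index
            for g in genes
            if any(kw.lower() in g.product.lower() for kw in query.exclude_keywords)
        }
        out -= excluded
    if not query.circular and any(s < query.radius or s >= n - query.radius for s in seeds):
        log.info("neighborhood windows truncated at the genome ends (linear gene order)")
    return sorted(out)
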
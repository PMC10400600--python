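"""Antisense ORF discovery on the reverse complement of annotated genes.

The scanner reads the reverse complement of each gene's sense strand and
reports, for every configured start codon occurring at least 14 bases in
(so a Shine-Dalgarno-proxy leader fits upstream), the open reading frame
extending to the first in-frame stop codon. Two modes are supported:

``leadered``
    every occurrence of every configured start codon seeds a candidate.
``startstop_motif``
    candidates are seeded only at the 4-mers ATGA, TTGA and GTGA, whose
    first three bases are a start codon overlapping an opal (TGA) stop —
    a motif common in leaderless bacterial genes.

All qualifying hits are reported, including multiple starts sharing one
stop (nested ORFs); ``first_per_stop`` collapses each (frame, stop) group
to its earliest start. Offsets are 0-based on the reverse-complement
strand and the reading frame is offset mod 3; ORF length in bases includes
the terminal stop codon, so length = 3 * (peptide length + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

from .codon_metrics import purine_fraction, reverse_complement

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODONS = ("ATG", "GTG", "TTG", "CTG", "ATA", "ATT", "ATC", "TAC")
STARTSTOP_MOTIFS = ("ATGA", "TTGA", "GTGA")

# Bacterial (translation table 11) codon assignments; no start->Met forcing.
_TABLE11 = CodonTable.unambiguous_dna_by_id[11].forward_table


@dataclass(frozen=True)
class AsorfParams:
    """Scanner parameters.

    ``min_codons`` counts body triplets between the start codon and the
    stop, so the minimum total ORF length is 3*min_codons + 6 bases. The
    default of 30 targets the small-protein regime; published summary
    tables used 90. ``min_leader_purine`` optionally drops hits whose
    14-base leader falls below a purine-fraction threshold (off by
    default).
    """

    start_codons: tuple[str, ...] = START_CODONS
    mode: str = "leadered"  # or "startstop_motif"
    min_codons: int = 30
    leader_len: int = 14
    min_leader_purine: float | None = None
    stop_codons: tuple[str, ...] = STOP_CODONS
    first_per_stop: bool = False

    def __post_init__(self) -> None:
        if not self.start_codons:
            raise ValueError("start codon set is empty")
        if self.min_codons < 1:
            raise ValueError("min_codons must be >= 1")
        if self.mode not in ("leadered", "startstop_motif"):
            raise ValueError(f"unknown mode {self.mode!r}")
        bad = set(self.start_codons) - set(START_CODONS)
        if bad:
            raise ValueError(f"unsupported start codons: {sorted(bad)}")


@dataclass(frozen=True)
class AsorfHit:
    """One putative antisense ORF.

    ``offset`` is the 0-based index of the start codon's first base on the
    reverse-complement strand; ``length_bases`` includes the terminal stop
    codon; ``nt_seq``/``aa_seq`` exclude the stop.
    """

    gene_id: str
    offset: int
    length_bases: int
    start_codon: str
    frame: int
    leader_seq: str
    leader_purine: float
    nt_seq: str
    aa_seq: str
    r1: float
    y2: float


def translate_literal(nt: str) -> str:
    """Literal codon-by-codon translation under the bacterial genetic code.

    No start-codon-to-Met substitution is applied (an ORF starting with TAC
    translates to Y...); codons containing non-ACGT symbols yield 'X'; an
    internal stop codon is an error naming the codon index.
    """
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise ValueError("nucleotide length must be a multiple of 3")
    aa = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon index {i // 3}")
        aa.append(_TABLE11.get(codon, "X"))
    return "".join(aa)


def classify_frame(offset: int) -> int:
    """Reading frame (0, +1, +2) of a start codon on its strand."""
    if offset < 0:
        raise ValueError("offset must be non-negative")
    return offset % 3


def overlap_class(frame: int) -> str:
    """Which sense codon base aligns with the same antisense codon base.

    Antisense frame 0 pairs base 2 with base 2 ("2-over-2"); frame +1 pairs
    base 3 with base 3 ("3-over-3"), forcing pyrimidines into base 2 of
    both strands when both have purine-biased base 1 (non-polar amino
    acids); frame +2 pairs base 1 with base 1 ("1-over-1"), infeasible when
    both strands carry a strong base-1 purine bias.
    """
    return {0: "2-over-2", 1: "3-over-3", 2: "1-over-1"}[frame]


def _next_stop_by_frame(rc: str, stop_codons: Sequence[str]) -> list[dict[int, int]]:
    """For each frame, map codon start index -> index of first in-frame stop."""
    L = len(rc)
    stops = set(stop_codons)
    table: list[dict[int, int]] = [{}, {}, {}]
    for f in range(3):
        nearest = -1
        start = f + 3 * ((L - 3 - f) // 3) if L - 3 >= f else None
        if start is None:
            continue
        for j in range(start, f - 1, -3):
            if rc[j : j + 3] in stops:
                nearest = j
            if nearest >= 0:
                table[f][j] = nearest
    return table


def _candidate_starts(rc: str, params: AsorfParams) -> list[tuple[int, str]]:
    cands: list[tuple[int, str]] = []
    if params.mode == "leadered":
        needles = [(sc, sc) for sc in params.start_codons]
    else:
        needles = [(motif, motif[:3]) for motif in STARTSTOP_MOTIFS]
    for needle, start_codon in needles:
        pos = rc.find(needle, params.leader_len)
        while pos != -1:
            cands.append((pos, start_codon))
            pos = rc.find(needle, pos + 1)
    return cands


def find_asorfs(gene, params: AsorfParams = AsorfParams()) -> list[AsorfHit]:
    """Scan one gene's reverse complement for putative antisense ORFs.

    Returns hits sorted by (offset, start codon). A gene too short to hold
    a minimal leadered ORF yields an empty list (logged, not an error).
    """
    gene_id = getattr(gene, "locus_tag", None) or str(getattr(gene, "gene_symbol", "gene"))
    seq = gene.seq if hasattr(gene, "seq") else str(gene)
    if len(seq) < params.leader_len + 3 * (params.min_codons + 2):
        log.info("gene %s too short for the configured minimal ORF; no scan", gene_id)
        return []
    rc = reverse_complement(seq)
    stop_lookup = _next_stop_by_frame(rc, params.stop_codons)

    hits: list[AsorfHit] = []
    for i, start_codon in _candidate_starts(rc, params):
        frame = i % 3
        stop = stop_lookup[frame].get(i + 3)
        if stop is None:
            continue
        body_codons = (stop - (i + 3)) // 3
        if body_codons < params.min_codons:
            continue
        leader = rc[i - params.leader_len : i]
        leader_purine = sum(b in "AG" for b in leader) / len(leader)
        if params.min_leader_purine is not None and leader_purine < params.min_leader_purine:
            continue
        nt = rc[i:stop]
        try:
            aa = translate_literal(nt)
        except ValueError:
            # N-containing codons translate to X; internal stops cannot occur
            # by construction, so only a malformed sequence reaches here.
            continue
        hits.append(
            AsorfHit(
                gene_id=gene_id,
                offset=i,
                length_bases=stop + 3 - i,
                start_codon=start_codon,
                frame=frame,
                leader_seq=leader,
                leader_purine=leader_purine,
                nt_seq=nt,
                aa_seq=aa,
                r1=purine_fraction(nt, 1),
                y2=1.0 - purine_fraction(nt, 2),
            )
        )

    if params.first_per_stop:
        best: dict[tuple[int, int], AsorfHit] = {}
        for h in hits:
            key = (h.frame, h.offset + h.length_bases)
            if key not in best or h.offset < best[key].offset:
                best[key] = h
        hits = list(best.values())

    hits.sort(key=lambda h: (h.offset, h.start_codon))
    return hits


@dataclass(frozen=True)
class AsorfSummary:
    """Aggregate statistics over a set of hits (one organism / gene set)."""

    n_genes_total: int
    n_genes_with_hits: int
    total_hits: int
    mean_length_bases: float
    hits_per_frame: dict[int, int]
    mean_leader_purine: float
    mean_r1: float
    mean_y2: float
    mean_r1_per_frame: dict[int, float]
    mean_y2_per_frame: dict[int, float]


def summarize_hits(hits: Sequence[AsorfHit], n_genes_total: int = 0) -> AsorfSummary:
    """Summary table over hits: counts, frame distribution, composition means."""
    if not hits:
        return AsorfSummary(
            n_genes_total=n_genes_total,
            n_genes_with_hits=0,
            total_hits=0,
            mean_length_bases=0.0,
            hits_per_frame={0: 0, 1: 0, 2: 0},
            mean_leader_purine=0.0,
            mean_r1=0.0,
            mean_y2=0.0,
            mean_r1_per_frame={0: 0.0, 1: 0.0, 2: 0.0},
            mean_y2_per_frame={0: 0.0, 1: 0.0, 2: 0.0},
        )

    def mean(vals: Iterable[float]) -> float:
        vals = list(vals)
        return float(np.mean(vals)) if vals else 0.0

    per_frame = {f: [h for h in hits if h.frame == f] for f in range(3)}
    return AsorfSummary(
        n_genes_total=n_genes_total,
        n_genes_with_hits=len({h.gene_id for h in hits}),
        total_hits=len(hits),
        mean_length_bases=mean(h.length_bases for h in hits),
        hits_per_frame={f: len(v) for f, v in per_frame.items()},
        mean_leader_purine=mean(h.leader_purine for h in hits),
        mean_r1=mean(h.r1 for h in hits),
        mean_y2=mean(h.y2 for h in hits),
        mean_r1_per_frame={f: mean(h.r1 for h in v) for f, v in per_frame.items()},
        mean_y2_per_frame={f: mean(h.y2 for h in v) for f, v in per_frame.items()},
    )
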
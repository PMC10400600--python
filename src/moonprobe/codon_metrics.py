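"""Per-gene codon composition statistics and ranking metrics.

All metrics read codons on the sense strand (or its reverse complement where
stated), ignore a trailing partial codon, and exclude any codon containing N
from both numerator and denominator. Two binary alphabets are used
throughout: RY (purine A/G vs pyrimidine C/T) and SW (strong G/C vs weak
A/T).

Metrics
-------
R1/R2/R3
    purine fraction at codon bases 1, 2, 3. R1 >= 0.6 is the classic
    reading-frame signal of protein-coding genes.
R1-rc
    R1 of the reverse-complement read in its own 5'->3' codons; high values
    in both directions suggest antisense coding potential.
RNY
    fraction of codons matching purine-any-pyrimidine, a pattern that is
    its own reverse complement (the anticodon of RNY is RNY).
dot score
    1 - cosine between the L2-normalized entropy vectors
    [H_RY1, H_RY3] and [H_SW1, H_SW3]; divergence between the RY and SW
    information channels at the degenerate codon bases.
combined score
    RNY + dot score (both terms lie in [0, 1]).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_ACGT = np.frombuffer(b"ACGT", dtype="S1")
_PURINES = np.frombuffer(b"AG", dtype="S1")
_STRONG = np.frombuffer(b"GC", dtype="S1")
_PYRIMIDINES = np.frombuffer(b"CT", dtype="S1")


@dataclass(frozen=True)
class CodonProfile:
    """Per-gene metric bundle. All fractions and entropies lie in [0, 1]."""

    r1: float
    r2: float
    r3: float
    r1_rc: float
    y2: float
    rny: float
    h_ry1: float
    h_ry3: float
    h_sw1: float
    h_sw3: float
    dot_score: float
    rnyplus_score: float
    combined_score: float
    n_codons: int

    FIELDS = (
        "r1", "r2", "r3", "r1_rc", "y2", "rny",
        "h_ry1", "h_ry3", "h_sw1", "h_sw3",
        "dot_score", "rnyplus_score", "combined_score", "n_codons",
    )


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _codon_array(seq: str) -> np.ndarray:
    """(n_codons, 3) byte matrix of N-free codons; trailing partial codon dropped."""
    seq = seq.upper()
    n = len(seq) // 3
    if n == 0:
        raise ValueError("sequence shorter than one codon")
    arr = np.frombuffer(seq[: 3 * n].encode("ascii"), dtype="S1").reshape(n, 3)
    valid = np.isin(arr, _ACGT).all(axis=1)
    out = arr[valid]
    if out.shape[0] == 0:
        raise ValueError("no codon free of ambiguous bases")
    return out


def purine_fraction(seq: str, base_position: int) -> float:
    """Fraction of codons with A or G at the given codon base (1, 2 or 3)."""
    if base_position not in (1, 2, 3):
        raise ValueError("base_position must be 1, 2 or 3")
    cod = _codon_array(seq)
    return float(np.isin(cod[:, base_position - 1], _PURINES).mean())


def reverse_complement_r1(seq: str) -> float:
    """Purine fraction at base one of reverse-complement codons."""
    return purine_fraction(reverse_complement(seq), 1)


def rny_fraction(seq: str) -> float:
    """Fraction of codons matching purine - any base - pyrimidine."""
    cod = _codon_array(seq)
    hits = np.isin(cod[:, 0], _PURINES) & np.isin(cod[:, 2], _PYRIMIDINES)
    return float(hits.mean())


def binary_entropy(f: float) -> float:
    """Two-symbol Shannon entropy in bits; H(0)=H(1)=0, H(0.5)=1."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {f}")
    h = 0.0
    for p in (f, 1.0 - f):
        if p > 0.0:
            h -= p * math.log2(p)
    return h


def _entropy_vectors(seq: str) -> tuple[np.ndarray, np.ndarray]:
    cod = _codon_array(seq)
    f_ry1 = float(np.isin(cod[:, 0], _PURINES).mean())
    f_ry3 = float(np.isin(cod[:, 2], _PURINES).mean())
    f_sw1 = float(np.isin(cod[:, 0], _STRONG).mean())
    f_sw3 = float(np.isin(cod[:, 2], _STRONG).mean())
    v_ry = np.array([binary_entropy(f_ry1), binary_entropy(f_ry3)])
    v_sw = np.array([binary_entropy(f_sw1), binary_entropy(f_sw3)])
    return v_ry, v_sw


def dot_score(seq: str) -> float:
    """1 - cosine of the RY and SW entropy vectors at codon bases 1 and 3.

    Each vector is L2-normalized before the dot product. If either vector
    has zero norm (composition perfectly biased on both bases), no RY/SW
    divergence is detectable and the score is defined as 0.
    """
    v_ry, v_sw = _entropy_vectors(seq)
    n_ry = np.linalg.norm(v_ry)
    n_sw = np.linalg.norm(v_sw)
    if n_ry == 0.0 or n_sw == 0.0:
        return 0.0
    cosine = float(np.dot(v_ry / n_ry, v_sw / n_sw))
    return float(min(1.0, max(0.0, 1.0 - cosine)))


def profile(gene_or_seq) -> CodonProfile:
    """Compute the full metric bundle for a Gene or a raw sequence."""
    seq = gene_or_seq if isinstance(gene_or_seq, str) else gene_or_seq.seq
    cod = _codon_array(seq)
    r1 = float(np.isin(cod[:, 0], _PURINES).mean())
    r2 = float(np.isin(cod[:, 1], _PURINES).mean())
    r3 = float(np.isin(cod[:, 2], _PURINES).mean())
    rny = float((np.isin(cod[:, 0], _PURINES) & np.isin(cod[:, 2], _PYRIMIDINES)).mean())
    r1_rc = reverse_complement_r1(seq)
    v_ry, v_sw = _entropy_vectors(seq)
    ds = dot_score(seq)
    return CodonProfile(
        r1=r1,
        r2=r2,
        r3=r3,
        r1_rc=r1_rc,
        y2=1.0 - r2,
        rny=rny,
        h_ry1=float(v_ry[0]),
        h_ry3=float(v_ry[1]),
        h_sw1=float(v_sw[0]),
        h_sw3=float(v_sw[1]),
        dot_score=ds,
        rnyplus_score=r1 + r1_rc,
        combined_score=rny + ds,
        n_codons=int(cod.shape[0]),
    )


def genome_summary(profiles: Sequence[CodonProfile], field: str) -> tuple[float, float]:
    """Unweighted per-gene mean and sample (n-1) standard deviation of a field.

    With a single profile the standard deviation is reported as 0 and a
    warning is logged (the sample convention is undefined at n = 1).
    """
    if not profiles:
        raise ValueError("empty profile list")
    vals = np.array([getattr(p, field) for p in profiles], dtype=float)
    mean = float(vals.mean())
    if len(vals) == 1:
        log.warning("genome_summary of a single profile: sd reported as 0")
        return mean, 0.0
    return mean, float(vals.std(ddof=1))


def codon_weighted_mean(profiles: Sequence[CodonProfile], field: str) -> float:
    """Codon-weighted alternative to the per-gene mean of ``genome_summary``."""
    if not profiles:
        raise ValueError("empty profile list")
    vals = np.array([getattr(p, field) for p in profiles], dtype=float)
    w = np.array([p.n_codons for p in profiles], dtype=float)
    return float((vals * w).sum() / w.sum())
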
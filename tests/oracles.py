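"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is written as naive per-position/per-codon enumeration,
deliberately avoiding the implementation's vectorized/scanning code paths.
"""

from math import comb

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def revcomp(seq):
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def loop_codons(seq):
    seq = seq.upper()
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        c = seq[i : i + 3]
        if all(b in "ACGT" for b in c):
            out.append(c)
    return out


def loop_purine_fraction(seq, base_position):
    cods = loop_codons(seq)
    hits = sum(1 for c in cods if c[base_position - 1] in "AG")
    return hits / len(cods)


def loop_rny_fraction(seq):
    cods = loop_codons(seq)
    hits = sum(1 for c in cods if c[0] in "AG" and c[2] in "CT")
    return hits / len(cods)


def hypergeom_tail_exact(N, K, n, k):
    """P(X >= k) by exhaustive binomial-coefficient summation."""
    total = comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        if n - j <= N - K:
            acc += comb(K, j) * comb(N - K, n - j)
    return acc / total


def brute_force_asorfs(seq, start_codons, min_codons, leader_len=14,
                       stops=("TAA", "TAG", "TGA"), motifs=None):
    """Scan every index of the reverse complement for qualifying ORFs.

    Returns (offset, start_codon, length_bases) tuples. When ``motifs`` is
    given, only positions where a start/stop 4-mer occurs seed candidates.
    """
    rc = revcomp(seq)
    out = []
    for i in range(leader_len, len(rc) - 2):
        if motifs is not None:
            if rc[i : i + 4] not in motifs:
                continue
            sc = rc[i : i + 3]
        else:
            sc = rc[i : i + 3]
            if sc not in start_codons:
                continue
        j = i + 3
        while j + 3 <= len(rc) and rc[j : j + 3] not in stops:
            j += 3
        if j + 3 > len(rc):
            continue  # ran off the end without a stop
        body = (j - (i + 3)) // 3
        if body >= min_codons:
            out.append((i, sc, j + 3 - i))
    return sorted(out)
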
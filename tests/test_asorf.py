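"""Antisense ORF scanner: hand-built cases, published-row conventions,
literal translation, and brute-force oracle equivalence."""

import random
from types import SimpleNamespace

import pytest

from moonprobe import (
    AsorfParams,
    classify_frame,
    find_asorfs,
    overlap_class,
    summarize_hits,
    translate_literal,
)
from moonprobe.codon_metrics import reverse_complement

from oracles import brute_force_asorfs

# Rows transcribed from published antisense-ORF hit tables:
# (gene, offset, length_bases, start_codon, frame)
PUBLISHED_ROWS = [
    ("dnaK_mtb", 270, 804, "TAC", 0),
    ("dnaK_mtb", 412, 222, "ATG", 1),
    ("glnA1", 613, 138, "ATG", 1),
    ("glnA1", 625, 126, "TTG", 1),
    ("iscS", 1075, 93, "CTG", 1),
    ("murI_ec", 170, 234, "CTG", 2),
    ("rpoB_ec", 87, 2892, "CTG", 0),
    ("tuf_ec", 55, 138, "ATT", 1),
    ("gpmB_ec", 316, 273, "GTG", 1),
    ("gpmB_ec", 358, 231, "GTG", 1),
]

# Shared-stop hit groups: within a group, offset + length is constant.
ACEB_GROUP = [(261, 408), (276, 393), (294, 375), (321, 348), (390, 279),
              (468, 201), (498, 171)]
RPOB_EC_FRAME0_GROUP = [(87, 2892), (90, 2889), (114, 2865), (165, 2814),
                        (579, 2400), (621, 2358), (681, 2298), (819, 2160)]

GLNA1_AA = "MPDPLSPNSGLGMNVTVLPFCQAVFLMMYLYNCMSSAACSSELNW"
ISCS_AA = "LVCSDDALPMVRCTAAIASMAAGCIGVVAA"


def gene_from_rc(rc, name="toy"):
    return SimpleNamespace(locus_tag=name, gene_symbol=name,
                           seq=reverse_complement(rc))


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestScanner:
    def test_hand_enumerated_single_hit(self):
        rc = "A" * 14 + "ATGGCCGTT" + "TAA"
        hits = find_asorfs(gene_from_rc(rc), AsorfParams(min_codons=1))
        assert len(hits) == 1
        h = hits[0]
        assert (h.offset, h.frame, h.length_bases, h.start_codon) == (14, 2, 12, "ATG")
        assert h.aa_seq == "MAV"
        assert h.nt_seq == "ATGGCCGTT"
        assert h.leader_seq == "A" * 14
        assert h.leader_purine == 1.0

    def test_no_stop_yields_no_hits(self):
        rc = "A" * 14 + "ATG" + "GCC" * 40  # no stop anywhere downstream
        assert find_asorfs(gene_from_rc(rc), AsorfParams(min_codons=1)) == []

    def test_start_without_leader_room_ignored(self):
        rc = "ATGGCCGTTTAA" + "C" * 30
        assert find_asorfs(gene_from_rc(rc), AsorfParams(min_codons=1)) == []

    def test_undersized_gene_returns_empty(self):
        g = gene_from_rc("ATGTAA")
        assert find_asorfs(g, AsorfParams(min_codons=30)) == []

    def test_nested_starts_share_one_stop(self):
        rc = "C" * 14 + "ATG" + "GTG" + "GCCGTT" + "TAA"
        hits = find_asorfs(gene_from_rc(rc), AsorfParams(min_codons=1))
        ends = {h.offset + h.length_bases for h in hits}
        assert len(hits) == 2
        assert len(ends) == 1  # same stop
        assert [h.start_codon for h in hits] == ["ATG", "GTG"]
        collapsed = find_asorfs(
            gene_from_rc(rc), AsorfParams(min_codons=1, first_per_stop=True)
        )
        assert len(collapsed) == 1 and collapsed[0].start_codon == "ATG"

    def test_motif_mode_requires_startstop_4mer(self):
        # ATG immediately followed by A forms the ATGA motif.
        rc_motif = "C" * 14 + "ATG" + "AAACCC" + "TAA"
        rc_plain = "C" * 14 + "ATG" + "CCCAAA" + "TAA"
        p = AsorfParams(mode="startstop_motif", min_codons=1)
        assert len(find_asorfs(gene_from_rc(rc_motif), p)) == 1
        assert find_asorfs(gene_from_rc(rc_plain), p) == []
        # leadered mode finds both
        p_lead = AsorfParams(min_codons=1)
        assert len(find_asorfs(gene_from_rc(rc_motif), p_lead)) == 1
        assert len(find_asorfs(gene_from_rc(rc_plain), p_lead)) == 1

    def test_min_codons_counts_body_triplets(self):
        rc = "C" * 14 + "ATG" + "GCC" * 5 + "TAA"
        assert len(find_asorfs(gene_from_rc(rc), AsorfParams(min_codons=5))) == 1
        assert find_asorfs(gene_from_rc(rc), AsorfParams(min_codons=6)) == []

    def test_leader_purine_filter(self):
        rc = "CT" * 7 + "ATGGCCGTTTAA"
        p_off = AsorfParams(min_codons=1)
        p_on = AsorfParams(min_codons=1, min_leader_purine=0.6)
        assert len(find_asorfs(gene_from_rc(rc), p_off)) == 1
        assert find_asorfs(gene_from_rc(rc), p_on) == []

    def test_deterministic(self):
        rng = random.Random(7)
        g = gene_from_rc(random_seq(rng, 900))
        p = AsorfParams(min_codons=3)
        assert find_asorfs(g, p) == find_asorfs(g, p)

    def test_matches_brute_force_oracle(self):
        rng = random.Random(8)
        p = AsorfParams(min_codons=2)
        for _ in range(60):
            seq = random_seq(rng, rng.randint(120, 1200))
            g = SimpleNamespace(locus_tag="r", gene_symbol="r", seq=seq)
            got = sorted((h.offset, h.start_codon, h.length_bases)
                         for h in find_asorfs(g, p))
            expected = brute_force_asorfs(seq, p.start_codons, p.min_codons)
            assert got == expected

    def test_motif_mode_matches_brute_force_oracle(self):
        rng = random.Random(9)
        p = AsorfParams(mode="startstop_motif", min_codons=2)
        for _ in range(40):
            seq = random_seq(rng, rng.randint(120, 1200))
            g = SimpleNamespace(locus_tag="r", gene_symbol="r", seq=seq)
            got = sorted((h.offset, h.start_codon, h.length_bases)
                         for h in find_asorfs(g, p))
            expected = brute_force_asorfs(seq, p.start_codons, p.min_codons,
                                          motifs=("ATGA", "TTGA", "GTGA"))
            assert got == expected


class TestConventions:
    @pytest.mark.parametrize("gene,offset,length,start,frame", PUBLISHED_ROWS)
    def test_frame_is_offset_mod_3(self, gene, offset, length, start, frame):
        assert classify_frame(offset) == frame

    @pytest.mark.parametrize("group,end", [(ACEB_GROUP, 669), (RPOB_EC_FRAME0_GROUP, 2979)])
    def test_shared_stop_groups_have_constant_end(self, group, end):
        for offset, length in group:
            assert offset + length == end

    @pytest.mark.parametrize(
        "length,aa", [(138, GLNA1_AA), (93, ISCS_AA), (222, None)]
    )
    def test_length_is_three_times_aa_plus_stop(self, length, aa):
        if aa is not None:
            assert length == 3 * (len(aa) + 1)
        assert length % 3 == 0

    def test_overlap_class_mapping(self):
        assert overlap_class(0) == "2-over-2"
        assert overlap_class(1) == "3-over-3"
        assert overlap_class(2) == "1-over-1"

    def test_scanner_hits_obey_conventions(self):
        rng = random.Random(10)
        g = SimpleNamespace(locus_tag="r", gene_symbol="r",
                            seq=random_seq(rng, 1500))
        for h in find_asorfs(g, AsorfParams(min_codons=2)):
            assert h.frame == h.offset % 3
            assert h.length_bases == 3 * (len(h.aa_seq) + 1)
            assert h.offset >= 14
            assert "*" not in h.aa_seq
            for i in range(0, len(h.nt_seq), 3):
                assert h.nt_seq[i:i + 3] not in ("TAA", "TAG", "TGA")


class TestTranslation:
    @pytest.mark.parametrize(
        "nt,aa",
        [("ATG", "M"), ("CTGGTG", "LV"), ("TAC", "Y"), ("ATA", "I"), ("GTG", "V")],
    )
    def test_literal_no_start_substitution(self, nt, aa):
        assert translate_literal(nt) == aa

    def test_published_alt_start_peptides(self):
        # an ORF starting CTG translates literally to L..., TAC to Y...
        assert ISCS_AA.startswith("LV")
        assert translate_literal("CTGGTGTGCAGCGAC") == "LVCSD"

    def test_internal_stop_names_codon_index(self):
        with pytest.raises(ValueError, match="codon index 1"):
            translate_literal("ATGTAGGCC")

    def test_ambiguous_codon_is_x(self):
        assert translate_literal("ATGNNTGCC") == "MXA"

    def test_frame_error(self):
        with pytest.raises(ValueError):
            translate_literal("ATGG")


class TestSummary:
    def test_empty_summary_is_all_zero(self):
        s = summarize_hits([], n_genes_total=5)
        assert s.total_hits == 0
        assert s.n_genes_with_hits == 0
        assert s.hits_per_frame == {0: 0, 1: 0, 2: 0}

    def test_means_over_synthetic_hits(self):
        rc_a = "C" * 14 + "ATG" + "GCC" * 4 + "TAA"
        rc_b = "C" * 14 + "ATG" + "TTT" * 4 + "TAA"
        hits = find_asorfs(gene_from_rc(rc_a, "a"), AsorfParams(min_codons=1))
        hits += find_asorfs(gene_from_rc(rc_b, "b"), AsorfParams(min_codons=1))
        s = summarize_hits(hits, n_genes_total=2)
        assert s.total_hits == 2
        assert s.n_genes_with_hits == 2
        assert s.mean_r1 == pytest.approx((hits[0].r1 + hits[1].r1) / 2)
        assert s.mean_length_bases == pytest.approx(18.0)
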
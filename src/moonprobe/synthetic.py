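"""Synthetic annotated genomes with controlled codon statistics.

Each codon base is sampled independently on the two binary axes — purine
vs pyrimidine (RY) with a per-position target fraction, and strong vs weak
(SW) with a per-position G+C target — which jointly determine the base
(purine+strong = G, purine+weak = A, pyrimidine+strong = C,
pyrimidine+weak = T). This gives direct control over R1/R2/R3, G+C and
(through base 1 and base 3) the RNY fraction, which is what the ranking
metrics probe; it does not emulate amino-acid usage, operon structure or
real codon-usage tables.

Antisense ORFs are planted verbatim into the reverse-complement strand of
chosen genes: a random 14-base leader, the start codon, a stop-free body,
and a stop codon, so a scanner must recover exactly the planted
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .asorf import STOP_CODONS
from .codon_metrics import reverse_complement
from .genome_io import Gene

log = logging.getLogger(__name__)

_SPACER = "ACGTACGTACGTACGTACGT"  # inter-gene filler in written fixtures


@dataclass(frozen=True)
class PlantedAsorf:
    """One antisense ORF to embed: coordinates are on the rc strand.

    ``length_bases`` includes the terminal stop codon and must be a
    multiple of 3 with at least one body triplet (length >= 9);
    ``motif_compatible`` forces the first body base to A so the plant also
    carries a start/stop 4-mer (ATGA/TTGA/GTGA) for motif-mode scanners.
    """

    gene_index: int
    offset: int
    length_bases: int
    start_codon: str = "ATG"
    stop_codon: str = "TAA"
    motif_compatible: bool = False

    def __post_init__(self) -> None:
        if self.offset < 14:
            raise ValueError("offset must leave room for a 14-base leader")
        if self.length_bases % 3 or self.length_bases < 9:
            raise ValueError("length_bases must be a multiple of 3 and >= 9")
        if self.stop_codon not in STOP_CODONS:
            raise ValueError(f"invalid stop codon {self.stop_codon!r}")


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic genome.

    Background composition defaults approximate a typical bacterial CDS
    genome: base-1 purine fraction 0.60 (the universal reading-frame
    signal), base-2 0.55, base-3 0.45, G+C 0.55 at every position. Genes
    listed in ``planted_set`` ("moonlighting-like") get composition with
    elevated RNY fraction and divergent RY/SW entropy vectors.
    ``category_labels`` assigns product-text labels to fractions of genes;
    unlabeled genes are annotated "uncharacterized protein".
    """

    n_genes: int = 60
    gene_length_range: tuple[int, int] = (300, 900)
    purine_by_base: tuple[float, float, float] = (0.60, 0.55, 0.45)
    gc_by_base: tuple[float, float, float] = (0.55, 0.55, 0.55)
    planted_set: tuple[int, ...] = ()
    planted_purine_by_base: tuple[float, float, float] = (0.85, 0.50, 0.15)
    planted_gc_by_base: tuple[float, float, float] = (0.50, 0.50, 0.90)
    category_labels: dict[str, float] = field(default_factory=dict)
    planted_asorfs: tuple[PlantedAsorf, ...] = ()
    minus_strand_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gene_length_range
        if lo % 3 or hi % 3 or lo < 30 or hi < lo:
            raise ValueError("gene_length_range bounds must be multiples of 3, >= 30")
        for fracs in (
            self.purine_by_base,
            self.gc_by_base,
            self.planted_purine_by_base,
            self.planted_gc_by_base,
        ):
            if any(not 0.0 <= f <= 1.0 for f in fracs):
                raise ValueError("composition targets must lie in [0, 1]")
        if any(i < 0 or i >= self.n_genes for i in self.planted_set):
            raise ValueError("planted_set index outside the genome")


def _sample_bases(rng, n: int, purine_by_base, gc_by_base) -> str:
    """Sample n codon-positioned bases from independent RY/SW Bernoullis."""
    pos = np.arange(n) % 3
    pur = rng.random(n) < np.asarray(purine_by_base)[pos]
    strong = rng.random(n) < np.asarray(gc_by_base)[pos]
    lut = np.array(list("TCAG"))  # index = 2*purine + strong
    return "".join(lut[2 * pur.astype(int) + strong.astype(int)])


def _random_stopfree_body(rng, n_codons: int, first_base: str | None) -> str:
    codons = []
    for i in range(n_codons):
        while True:
            c = "".join(rng.choice(list("ACGT"), size=3))
            if i == 0 and first_base is not None:
                c = first_base + c[1:]
            if c not in STOP_CODONS:
                codons.append(c)
                break
    return "".join(codons)


def generate_genome(spec: SynthSpec) -> tuple[list[Gene], dict]:
    """Generate an annotated gene list plus a ground-truth record.

    The truth record maps ``category_members`` (label -> index list),
    ``planted_set`` and ``planted_asorfs`` (with the exact hit geometry a
    scanner should recover: offset, length, start codon, frame).
    Deterministic for a fixed spec (same seed -> identical genome).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gene_length_range
    lengths = (rng.integers(lo // 3, hi // 3 + 1, size=spec.n_genes) * 3).tolist()

    plants_by_gene: dict[int, list[PlantedAsorf]] = {}
    for p in spec.planted_asorfs:
        plants_by_gene.setdefault(p.gene_index, []).append(p)

    # Assign category labels to disjoint index blocks by fraction.
    unassigned = [i for i in range(spec.n_genes)]
    rng.shuffle(unassigned)
    category_members: dict[str, list[int]] = {}
    cursor = 0
    for label, frac in spec.category_labels.items():
        count = int(round(frac * spec.n_genes))
        category_members[label] = sorted(unassigned[cursor : cursor + count])
        cursor += count

    label_of: dict[int, str] = {
        i: label for label, members in category_members.items() for i in members
    }

    genes: list[Gene] = []
    planted_truth: list[dict] = []
    for i in range(spec.n_genes):
        L = lengths[i]
        planted_here = plants_by_gene.get(i, [])
        for p in planted_here:
            if p.offset + p.length_bases > L:
                L = 3 * ((p.offset + p.length_bases + 29) // 3)  # grow to fit
        if i in spec.planted_set:
            fwd = _sample_bases(rng, L, spec.planted_purine_by_base, spec.planted_gc_by_base)
        else:
            fwd = _sample_bases(rng, L, spec.purine_by_base, spec.gc_by_base)
        if planted_here:
            rc = list(reverse_complement(fwd))
            occupied: list[tuple[int, int]] = []
            for p in sorted(planted_here, key=lambda q: q.offset):
                span = (p.offset - 14, p.offset + p.length_bases)
                if any(a < span[1] and span[0] < b for a, b in occupied):
                    raise ValueError(f"overlapping planted asORFs in gene {i}")
                occupied.append(span)
                leader = "".join(rng.choice(list("ACGT"), size=14))
                n_body = p.length_bases // 3 - 2
                body = _random_stopfree_body(
                    rng, n_body, "A" if p.motif_compatible else None
                )
                insert = leader + p.start_codon + body + p.stop_codon
                rc[p.offset - 14 : p.offset + p.length_bases] = list(insert)
                planted_truth.append(
                    {
                        "gene_index": i,
                        "offset": p.offset,
                        "length_bases": p.length_bases,
                        "start_codon": p.start_codon,
                        "frame": p.offset % 3,
                        "n_body_codons": n_body,
                    }
                )
            fwd = reverse_complement("".join(rc))
        label = label_of.get(i)
        product = f"{label} protein {i}" if label else f"uncharacterized protein {i}"
        if i in spec.planted_set:
            product = f"moonlighting-like {product}"
        genes.append(
            Gene(
                locus_tag=f"SYN_{i:04d}",
                gene_symbol=f"syg{i:04d}",
                product=product,
                order_index=i,
                strand="-" if rng.random() < spec.minus_strand_fraction else "+",
                seq=fwd,
            )
        )

    truth = {
        "category_members": category_members,
        "planted_set": sorted(spec.planted_set),
        "planted_asorfs": planted_truth,
        "seed": spec.seed,
    }
    return genes, truth


def default_fixture_spec(seed: int = 0) -> SynthSpec:
    """The shipped 60-gene fixture: 6 moonlighting-like genes, category
    labels mirroring the neighborhood-assay tables, and 4 planted antisense
    ORFs (one per reading frame plus one start/stop-motif plant)."""
    return SynthSpec(
        n_genes=60,
        planted_set=(5, 12, 23, 34, 45, 56),
        category_labels={
            "cell wall biogenesis": 0.10,
            "secretion": 0.08,
            "inner membrane": 0.05,
            "fatty acid": 0.08,
            "peptidoglycan": 0.05,
            "hypothetical": 0.20,
        },
        planted_asorfs=(
            PlantedAsorf(gene_index=5, offset=30, length_bases=120, start_codon="ATG"),
            PlantedAsorf(gene_index=12, offset=25, length_bases=150, start_codon="GTG"),
            PlantedAsorf(gene_index=23, offset=20, length_bases=120, start_codon="CTG"),
            PlantedAsorf(
                gene_index=34, offset=33, length_bases=135, start_codon="TTG",
                motif_compatible=True,
            ),
        ),
        seed=seed,
    )


def write_fixture(genes, path, format: str = "genbank") -> list[Path]:
    """Write genes as a single-contig GenBank or GFF3+FASTA fixture.

    Genes are laid out in order, separated by a fixed 20-base spacer;
    minus-strand genes are stored reverse-complemented in the contig so
    parsing recovers the original sense sequences. Returns the paths
    written (GFF3 format writes two files).
    """
    if not genes:
        raise ValueError("cannot write a fixture with no genes")
    path = Path(path)

    contig_parts: list[str] = []
    locations: list[tuple[int, int]] = []
    pos = 0
    for g in genes:
        contig_parts.append(_SPACER)
        pos += len(_SPACER)
        placed = g.seq if g.strand == "+" else reverse_complement(g.seq)
        contig_parts.append(placed)
        locations.append((pos, pos + len(placed)))  # 0-based half-open
        pos += len(placed)
    contig_parts.append(_SPACER)
    contig = "".join(contig_parts)

    if format == "genbank":
        rec = SeqRecord(Seq(contig), id="synthetic1", name="synthetic1",
                        description="synthetic fixture genome")
        rec.annotations["molecule_type"] = "DNA"
        for g, (start, end) in zip(genes, locations):
            feat = SeqFeature(
                FeatureLocation(start, end, strand=1 if g.strand == "+" else -1),
                type="CDS",
                qualifiers={
                    "locus_tag": [g.locus_tag],
                    "gene": [g.gene_symbol],
                    "product": [g.product],
                },
            )
            rec.features.append(feat)
        SeqIO.write([rec], str(path), "genbank")
        return [path]

    if format in ("gff3", "gff3+fasta"):
        gff_path = path if path.suffix in (".gff", ".gff3") else path.with_suffix(".gff3")
        fasta_path = gff_path.with_suffix(".fa")
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region synthetic1 1 {len(contig)}\n")
            for g, (start, end) in zip(genes, locations):
                attrs = (
                    f"ID=cds-{g.locus_tag};locus_tag={g.locus_tag};"
                    f"gene={g.gene_symbol};product={g.product}"
                )
                fh.write(
                    "\t".join(
                        [
                            "synthetic1", "moonprobe", "CDS",
                            str(start + 1), str(end),  # 1-based inclusive
                            ".", g.strand, "0", attrs,
                        ]
                    )
                    + "\n"
                )
        SeqIO.write(
            [SeqRecord(Seq(contig), id="synthetic1", description="synthetic fixture")],
            str(fasta_path),
            "fasta",
        )
        return [gff_path, fasta_path]

    raise ValueError(f"unknown fixture format {format!r}")
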
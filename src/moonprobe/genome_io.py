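"""Read annotated genomes into ordered CDS gene lists; write peptide FASTA.

Internal sequences are plain uppercase strings over {A,C,G,T,N}; ambiguity
codes other than N are mapped to N at parse time. Minus-strand features are
reverse-complemented so that ``Gene.seq`` is always the coding (sense)
strand. Genomic base coordinates are not retained beyond the gene-order
index: every downstream analysis is gene-order- or sequence-local.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_NON_ACGT = re.compile(r"[^ACGT]")


class GenomeFormatError(ValueError):
    """Raised when an input file does not parse under the named standard."""


@dataclass(frozen=True)
class Gene:
    """One annotated CDS.

    ``seq`` is the sense strand 5'->3' regardless of genomic strand;
    ``order_index`` is the 0-based position in genome feature order.
    """

    locus_tag: str
    gene_symbol: str
    product: str
    order_index: int
    strand: str  # "+" or "-"
    seq: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if _NON_ACGT.search(self.seq.replace("N", "")):
            raise ValueError(f"{self.locus_tag}: seq alphabet must be A/C/G/T/N")


@dataclass(frozen=True)
class CategoryMap:
    """Ordered mapping of functional-category name -> product keywords.

    Matching is case-insensitive substring search over ``Gene.product`` and
    ``Gene.gene_symbol``; category names in published enrichment tables
    (e.g. "Cell wall biogenesis", "Hypothetical protein") are realized as
    keyword lists over RefSeq product strings.
    """

    entries: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, kws in self.entries.items():
            if not kws:
                raise ValueError(f"category {name!r} has an empty keyword list")

    def items(self):
        return self.entries.items()


@dataclass(frozen=True)
class GeneSet:
    """A curated set of genes named by symbols and/or product keywords."""

    name: str
    match_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.match_terms:
            raise ValueError(f"gene set {self.name!r} has no match terms")


def clean_sequence(seq: str) -> str:
    """Uppercase and map every non-ACGT symbol to N."""
    return _NON_ACGT.sub("N", seq.upper())


def _gene_matches(gene: Gene, terms: Iterable[str]) -> bool:
    sym = gene.gene_symbol.lower()
    prod = gene.product.lower()
    return any(t.lower() in sym or t.lower() in prod for t in terms)


# ---------------------------------------------------------------------------
# Parsing


def parse_genome(path, format: str = "genbank", fasta=None) -> list[Gene]:
    """Parse an annotated genome into an ordered list of CDS Genes.

    Parameters
    ----------
    path : path to a GenBank flat file, or to a GFF3 file when
        ``format="gff3"`` (in which case ``fasta`` must name the genomic
        FASTA).
    format : {"genbank", "gff3"}

    Pseudo-genes and CDS features without an extractable sequence are
    skipped with a logged warning. Minus-strand sequences are
    reverse-complemented; compound (join) locations are concatenated in
    feature order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        return _parse_genbank(path)
    if format in ("gff3", "gff3+fasta", "gff"):
        if fasta is None:
            raise ValueError("GFF3 input requires the genomic FASTA via fasta=")
        return _parse_gff3(path, Path(fasta))
    raise ValueError(f"unknown genome format {format!r}")


def _qual(feature, key: str, default: str = "") -> str:
    vals = feature.qualifiers.get(key)
    return vals[0] if vals else default


def _parse_genbank(path: Path) -> list[Gene]:
    genes: list[Gene] = []
    order = 0
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # malformed flat file
        raise GenomeFormatError(f"{path}: not a parseable GenBank file ({exc})") from exc
    if not records:
        raise GenomeFormatError(f"{path}: no GenBank records found")
    for rec in records:
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            tag = _qual(feat, "locus_tag") or _qual(feat, "gene") or f"CDS_{order}"
            if "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers:
                log.warning("skipping pseudo-gene %s", tag)
                continue
            if feat.location is None:
                log.warning("skipping CDS %s without coordinates", tag)
                continue
            if int(feat.location.end) > len(rec.seq):
                log.error("CDS %s extends past contig end; skipped", tag)
                continue
            try:
                seq = str(feat.extract(rec.seq))
            except Exception as exc:
                log.warning("skipping CDS %s: sequence not extractable (%s)", tag, exc)
                continue
            if not seq:
                log.warning("skipping CDS %s: empty sequence", tag)
                continue
            strand = "-" if feat.location.strand == -1 else "+"
            genes.append(
                Gene(
                    locus_tag=tag,
                    gene_symbol=_qual(feat, "gene"),
                    product=_qual(feat, "product"),
                    order_index=order,
                    strand=strand,
                    seq=clean_sequence(seq),
                )
            )
            order += 1
    if any(len(g.seq) % 3 for g in genes):
        log.info("some gene lengths are not multiples of 3; trailing partial codons are ignored by codon tallies")
    return genes


def _attr(feature, *keys: str, default: str = "") -> str:
    for key in keys:
        vals = feature.attributes.get(key)
        if vals:
            return vals[0]
    return default


def _parse_gff3(gff_path: Path, fasta_path: Path) -> list[Gene]:
    try:
        db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise GenomeFormatError(f"{gff_path}: not a parseable GFF3 file ({exc})") from exc
    try:
        contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    except Exception as exc:
        raise GenomeFormatError(f"{fasta_path}: not a parseable FASTA file ({exc})") from exc
    if not contigs:
        raise GenomeFormatError(f"{fasta_path}: no FASTA records found")

    # Group CDS segments of one gene (GFF3 join semantics share an ID).
    groups: dict[str, list] = {}
    group_order: list[str] = []
    for i, feat in enumerate(db.features_of_type("CDS", order_by=("seqid", "start"))):
        gid = _attr(feat, "ID") or f"cds-{i}"
        if gid not in groups:
            groups[gid] = []
            group_order.append(gid)
        groups[gid].append(feat)

    genes: list[Gene] = []
    order = 0
    for gid in group_order:
        feats = sorted(groups[gid], key=lambda f: f.start)
        first = feats[0]
        tag = _attr(first, "locus_tag", "Name") or gid
        if _attr(first, "pseudo").lower() == "true" or "pseudogene" in _attr(first, "gene_biotype"):
            log.warning("skipping pseudo-gene %s", tag)
            continue
        contig = contigs.get(first.seqid)
        if contig is None:
            log.warning("skipping CDS %s: contig %s missing from FASTA", tag, first.seqid)
            continue
        if any(f.end > len(contig) for f in feats):
            log.error("CDS %s extends past contig end; skipped", tag)
            continue
        # GFF3 coordinates are 1-based inclusive.
        parts = [contig[f.start - 1 : f.end] for f in feats]
        seq = "".join(parts)
        if first.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        if not seq:
            log.warning("skipping CDS %s: empty sequence", tag)
            continue
        genes.append(
            Gene(
                locus_tag=tag,
                gene_symbol=_attr(first, "gene"),
                product=_attr(first, "product"),
                order_index=order,
                strand="-" if first.strand == "-" else "+",
                seq=clean_sequence(seq),
            )
        )
        order += 1
    return genes


# ---------------------------------------------------------------------------
# Gene-set matching


def match_gene_set(genes: Sequence[Gene], gene_set: GeneSet) -> list[int]:
    """Indices of genes matching any term, case-insensitively.

    Every annotated isoform whose symbol or product matches a curated term
    counts separately (isoform counting rule), so e.g. a "superoxide
    dismutase" term returns both *sodA* and *sodC*.
    """
    if not gene_set.match_terms:
        raise ValueError("gene set has no match terms")
    return sorted(g.order_index for g in genes if _gene_matches(g, gene_set.match_terms))


def match_category(genes: Sequence[Gene], keywords: Iterable[str]) -> set[int]:
    """Indices of genes whose symbol or product contains any keyword."""
    kws = list(keywords)
    return {g.order_index for g in genes if _gene_matches(g, kws)}


# ---------------------------------------------------------------------------
# Output


def write_peptides(hits, path) -> None:
    """Write antisense-ORF peptides as 60-column-wrapped FASTA.

    Headers encode gene id, offset, length, start codon and frame so that
    hits remain identifiable after a round trip through an external
    transmembrane-topology predictor.
    """
    records = []
    for h in hits:
        if not h.aa_seq:
            raise ValueError(f"hit at offset {h.offset} in {h.gene_id} has empty peptide")
        rid = f"{h.gene_id}|offset={h.offset}|len={h.length_bases}|start={h.start_codon}|frame={h.frame}"
        records.append(SeqRecord(Seq(h.aa_seq), id=rid, description=""))
    if not records:
        log.warning("no hits: writing empty peptide FASTA to %s", path)
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Configuration


def _default_config_path() -> Path:
    from importlib.resources import files

    return Path(str(files("moonprobe").joinpath("data/default_config.yaml")))


def load_config(path=None) -> tuple[CategoryMap, dict[str, GeneSet]]:
    """Load category keywords and curated gene sets from YAML (or JSON).

    The shipped default configuration encodes the functional-category names
    used in the enrichment tables and the curated moonlighting gene list.
    Schema: two top-level sections, ``categories`` (name -> keyword list)
    and ``gene_sets`` (name -> term list).
    """
    cfg_path = Path(path) if path is not None else _default_config_path()
    with open(cfg_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "categories" not in raw or "gene_sets" not in raw:
        raise ValueError(f"{cfg_path}: config must contain 'categories' and 'gene_sets'")
    categories = CategoryMap(entries={k: list(v) for k, v in raw["categories"].items()})
    gene_sets = {
        name: GeneSet(name=name, match_terms=tuple(terms))
        for name, terms in raw["gene_sets"].items()
    }
    return categories, gene_sets
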
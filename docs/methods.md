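# Methods

## Model and rationale

The package operationalizes a simple idea: if a gene encodes information in
both strand directions, the constraint shows up in codon composition. Most
protein-coding genes carry a strong purine bias at codon base 1 (R1 ≈ 0.6).
Because a purine can never pair with a purine, an antisense reading frame
overlapping a purine-biased sense frame is only freely compatible in some
alignments: antisense frame 0 aligns base 2 with base 2 ("2-over-2"),
frame +1 aligns base 3 with base 3 ("3-over-3", which forces pyrimidines
into base 2 of both strands and hence non-polar, membrane-friendly amino
acids), and frame +2 aligns base 1 with base 1 ("1-over-1", infeasible when
both strands are purine-biased at base 1). Genes with bidirectional coding
potential are therefore expected to show high RNY codon content (the RNY
pattern is its own reverse complement), high purine bias in both the
forward and reverse-complement base-1 positions, and divergent usage of the
RY and SW information channels at the degenerate codon bases 1 and 3.

Each metric is a per-gene scalar; the probe is the composition of
(1) metric ranking, (2) a top-fraction cut, and (3) hypergeometric
over-representation statistics for functional categories and curated gene
sets, optionally preceded by (4) a gene-order neighborhood sample, plus
(5) an explicit antisense-ORF scanner whose peptides can be screened for
transmembrane segments by an external predictor.

## Metric definitions and numerical conventions

* Codons are read in-frame from the 5′ end; a trailing partial codon is
  ignored; any codon containing N is excluded from numerator and
  denominator of every fraction. A sequence with no clean codon is a
  domain error.
* `binary_entropy(f)` is the standard two-symbol Shannon entropy in bits,
  −f·log₂f − (1−f)·log₂(1−f) with 0·log₂0 ≔ 0.
* `dot_score`: v_RY = [H(RY₁), H(RY₃)], v_SW = [H(SW₁), H(SW₃)], each
  L2-normalized; score = 1 − v_RY·v_SW, clamped to [0, 1] against floating
  point. If either vector has zero norm (composition perfectly biased at
  both bases), the cosine is undefined; we define the score as 0, the
  conservative choice — such genes are not promoted by the metric.
* `combined_score = rny + dot_score`, unweighted; both terms lie in [0, 1]
  so no rescaling is applied. `rnyplus_score = r1 + r1_rc` is the
  bidirectional purine-bias metric.
* `genome_summary` reports the unweighted per-gene mean and the sample
  (n−1) standard deviation; a codon-weighted mean is available as
  `codon_weighted_mean` for sensitivity analysis. At n = 1 the sd is
  reported as 0 with a warning.
* Fraction/entropy computations are vectorized (numpy byte matrices); the
  test suite checks them against naive per-codon loops.

## Enrichment assay

* Ranking sorts descending by score with ties broken by ascending gene
  order index — deterministic and stable across runs.
* Cut size is ⌊cut_fraction·N⌋ (a 20% cut of 3906 genes is exactly 781
  genes). The 20% default is inclusive yet conservative; smaller cuts give
  larger folds.
* E is the upper tail P(X ≥ k) *including* the observed count, the standard
  over-representation convention; it is computed from log-gamma terms with
  log-sum-exp for stability, and validated against exhaustive
  binomial-coefficient summation and an independent library implementation.
* The population N for every assay is the full CDS gene list — including
  the neighborhood assay, where the sample may have been filtered (e.g.
  hypothetical proteins removed) but category totals and N stay
  genome-wide. This is required for the fold arithmetic of filtered
  neighborhood tables to be self-consistent.
* Category membership is case-insensitive substring matching of keyword
  lists over product annotations and gene symbols; curated gene sets use
  the same rule, so every annotated isoform matching a curated name counts
  separately. Keyword lists are a reconstruction: annotation wording varies
  across RefSeq releases, so category totals are release-sensitive.
* E-values are reported raw (no multiple-testing correction), matching the
  assay's reporting convention; users comparing many categories should
  correct downstream.

## Neighborhood sampling

Windows of ±radius genes (default 5) around each seed gene are unioned and
deduplicated; seeds themselves are excluded unless requested. The genome is
treated as linear in gene order — wrap-around at the origin of a circular
chromosome is available behind a flag and affects at most `radius` genes.
Filtering (default: products containing "hypothetical protein") applies to
the sample only, per the population convention above.

## Antisense ORF scanner

* The scan operates on the reverse complement of each gene's sense strand;
  hits never span gene boundaries (a stated limitation — antisense ORFs
  crossing into intergenic sequence or neighboring genes are not found).
* Leadered mode seeds a candidate at every occurrence of every configured
  start codon at index ≥ 14 so that a 14-base leader fits; the leader's
  purine fraction is always reported as a Shine–Dalgarno proxy, but no
  leader filter is applied by default (an optional threshold exists).
* Start/stop-motif mode seeds only at ATGA/TTGA/GTGA 4-mers, whose bases
  1–3 are a start codon overlapping an opal TGA stop — a motif of
  leaderless genes.
* Extension proceeds in steps of 3 to the *first* in-frame stop wholly
  inside the sequence; `min_codons` (default 30, the small-protein regime;
  genome-survey summaries elsewhere in the package's reproduction script
  use 90) counts body triplets between start and stop, so the minimal ORF
  is 3·min_codons + 6 bases.
* All qualifying hits are reported, including multiple starts sharing one
  stop — nested ORF candidates are real objects of interest, and a
  resume-after-match scanner would silently drop them. `first_per_stop`
  collapses each (frame, stop) group to its earliest start.
* Conventions: offset is the 0-based index of the start codon's first base
  on the rc strand; frame = offset mod 3; length includes the terminal
  stop, so length = 3·(peptide length + 1). Hits within one gene ending at
  the same stop satisfy offset + length = constant.
* Translation is literal under the bacterial genetic code (translation
  table 11): no start-codon→Met substitution (a TAC start translates as Y),
  ambiguous codons yield X, and the per-hit R1/Y2 composition excludes the
  stop codon.
* The scanner is validated against a brute-force every-position oracle on
  random sequences up to 2 kb.

## Synthetic genomes

The generator samples each codon base independently on the RY axis (target
purine fraction per codon position) and the SW axis (target G+C per
position); the two bits determine the base. Defaults emulate a typical
bacterial CDS genome: purine fractions (0.60, 0.55, 0.45) at bases 1–3 and
G+C 0.55 — so the background RNY fraction is ≈ 0.60·0.55 ≈ 0.33.
"Moonlighting-like" genes get (0.85, 0.50, 0.15) with per-position G+C
(0.50, 0.50, 0.90), which elevates both the RNY fraction (≈ 0.72) and the
RY/SW entropy-vector divergence. Planted antisense ORFs are written
verbatim into the reverse-complement strand (random 14-base leader, start
codon, stop-free body, stop codon), so a correct scanner must recover
exactly the planted coordinates; a `motif_compatible` flag makes the first
body base an A so the plant also carries a start/stop 4-mer.

What the generator does *not* emulate: real codon-usage tables, amino-acid
composition, operon and strand structure, intergenic regulatory sequence,
and annotation noise. Passing the planted-recovery and analytic-fold tests
therefore demonstrates the probe's correctness as an algorithm, not the
biological effect size on real genomes — for that, the reproduction script
runs the identical pipeline on user-supplied RefSeq genomes.

The shipped fixture is 60 genes (300–900 bp) with six planted
moonlighting-like genes, category labels mirroring the neighborhood-assay
categories, and four planted antisense ORFs covering all three reading
frames plus one motif-mode plant. Problem sizes in the test suite (60-gene
genomes, 500 random sequences ≤ 2 kb for the scanner oracle, full
hypergeometric enumeration to N = 60) were chosen so the whole suite runs
in about a minute on one CPU while still exercising every code path at
meaningful scale.

## Design choices that were genuinely open

* **Tail convention**: "cumulative hypergeometric probability" admits ≥ k
  or > k; we use ≥ k, and a test shows only the inclusive tail reproduces
  the reference value 0.005 at (N, K, n, k) = (3906, 35, 781, 14).
* **Entropy formula**: the metric is defined as the standard two-symbol
  Shannon entropy; degenerate renderings of the formula in secondary
  sources are not mathematically usable.
* **Zero-norm entropy vectors** score 0 (see above).
* **Gene-order coordinates**: genomic base coordinates are dropped after
  parsing; all analyses are gene-order- or sequence-local, so retaining
  them would only invite misuse.
* **Cut arithmetic**: floor, not round — the only convention that yields a
  781-gene 20% cut of 3906.
* **CLI vs library**: every subcommand is a thin wrapper; TSV outputs are
  byte-identical to what the API produces, which the CLI tests assert.

## Known limitations

* Category keyword lists and curated gene-set terms cannot be pinned to a
  specific RefSeq release; counts on real genomes drift with annotation
  versions.
* Antisense ORFs spanning gene boundaries, antisense promoter structure,
  and Shine–Dalgarno modeling beyond leader purine content are out of
  scope, as is transmembrane prediction itself (peptides are exported for
  an external consensus predictor).
* The hypergeometric model assumes exchangeable genes; operon structure and
  local GC variation violate this mildly in real genomes.
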
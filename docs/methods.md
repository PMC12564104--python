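# Methods

## The problem

Plastid transcripts in land plants undergo C→U RNA editing (rarely U→C),
typically restoring conserved codons in photosynthesis- and
NDH-complex-related genes. Detecting these sites from strand-specific
RNA-seq means distinguishing a genuine transcript-strand C→U signal from
four recurrent classes of technical artifact:

1. **Splice-junction misalignment.** Reads spanning exon–intron boundaries
   generate spurious mismatches within a few bases of splice sites.
2. **dUTP second-strand carryover.** Incomplete USER-enzyme degradation of
   the dUTP-marked second cDNA strand leaves a faint opposite-strand signal
   that is the exact reverse complement of a real coding-strand edit (G→A
   mirroring C→U), at per-read rates orders of magnitude below the
   coding-strand editing efficiency.
3. **rRNA-modification misincorporation.** Reverse transcriptase reading
   across modified rRNA bases produces a diverse, multi-type substitution
   spectrum confined to rRNA loci, predominantly on the noncoding strand —
   canonical C→U is only a small minority of such calls.
4. **Strand misassignment.** A caller can report a C→U event as G→A on the
   strand opposite the gene even though the coding strand carries the
   dominant signal.

`plastedit` implements the full desk-scale pipeline: strand-aware candidate
calling from per-base pileups, flag-based artifact classification, codon
annotation on spliced CDS coordinates, and cross-sample/cross-library
reproducibility synthesis, plus a synthetic-data generator that emulates
the signal and artifact structure so every stage is testable against a
known truth set.

## Pipeline model and assumptions

**Pileups.** The unit of evidence is a per-(sample, library, position,
strand) vector of base counts. Counts are strand-local (transcript
orientation): on a minus-strand record, `nC` counts reads whose base is C
read 5'→3' along the minus strand. The optional SAM/BAM converter follows
the dUTP RF convention (mate 1 antisense to the transcript), counts only
primary, unique (MAPQ ≥ 1 by default), non-duplicate alignments, and
complements bases on minus-strand fragments to keep the dialect
strand-local.

**Calling.** Per strand record, the highest-count non-reference base is a
candidate iff supporting reads ≥ 3 and VAF ≥ 0.10, where the VAF
denominator is the full strand depth (all four bases). The reference base
on the minus strand is the complement of the plastome-forward base, so
substitutions are always expressed in transcript orientation. A relaxed
query (≥ 1 read, any positive VAF) recovers sub-threshold evidence; the
reproducibility stage uses it to distinguish "present below threshold"
from "absent". Called sets are monotone non-increasing in both thresholds.

**Artifact flags, not deletions.** Each filter sets a flag computed only
from the candidate set, pileups and gene models, so the flagging operations
commute and are idempotent; exclusion policy is applied once, at the
high-confidence stage, keeping every decision auditable.

- *Junction*: flag any call within `junction_window` (default 10 bp) of an
  exon–intron boundary. No published window exists for this class; 10 bp
  comfortably covers the misalignment footprint of 150 bp reads around
  short indel-free junctions and is exposed as an option.
- *rRNA*: region classification by position (priority CDS > rRNA > tRNA >
  UTR5 > UTR3 > intron > intergenic); all rRNA-locus calls are excluded
  from the final set regardless of substitution type, because the
  modification-driven spectrum there makes even canonical-looking C→U
  calls unreliable.
- *Noncanonical*: anything other than transcript-orientation C→T or T→C.
- *Carryover*: an opposite-strand call whose substitution is the reverse
  complement of the local gene's coding-strand signal, with opposite/coding
  VAF ratio ≤ `max_opposite_ratio` (default 0.10, bracketing the observed
  1/2840–1/63 range with margin). Because one or two stray reads at
  shallow antisense depth can inflate the plug-in ratio far above the true
  carryover rate (2 reads at depth 49 give VAF 0.041 even when the true
  rate is ~0.003), the detector also flags a shadow whose read count is
  statistically consistent — one-sided binomial tail probability ≥ 0.01 —
  with a carryover rate of `max_opposite_ratio` × coding VAF. Coding-strand
  calls are never flagged by this rule.
- *Strand discordance*: opposite-strand variant reads over total variant
  reads on both strands; > 0.10 marks "needs inspection", not rejection.
  The denominator (variant reads on both strands) is this package's
  definition.
- *Strand reassignment* (a rewrite, run before flagging): a G→A call
  antisense to a gene whose coding strand shows the complementary C→T at
  strictly higher VAF is re-expressed as C→T on the coding strand. Two
  guards separate this from physical carryover: the antisense call must
  itself carry ≥ 3 supporting reads (a misassigned caller report carries
  the full signal's support), and its VAF must exceed
  `max_opposite_ratio` × coding VAF (below that it is consistent with
  carryover and left to the carryover detector). The rewrite is
  involution-safe: applying it twice equals applying it once.

**Codon annotation.** "Position on gene" is 1-based on the spliced CDS
(concatenated exons in translation orientation; minus-strand genes
reverse-complemented), so codon index and codon position follow from
`pos = 3·(index−1) + position`. Translation uses the standard genetic code
with no start-codon special-casing (an edited ACG→ATG start is reported as
T→M). A site whose transcript-orientation reference base disagrees with
the genome is a hard error — it signals a coordinate bug, not data noise.

**Cross-sample harmonization.** Samples are called against their own
assemblies; a whole-plastome multiple alignment (e.g. MAFFT output) gives
each sample a bijection between genome positions and alignment columns.
Sites are keyed by (column, strand, substitution); positions falling in a
sample's gap get status "absent" with a `no_counterpart` note. Features
may not wrap the origin: assembled plastomes are consumed linearized.

**High-confidence set.** Retain sites that are canonical, non-rRNA,
coding-strand, free of junction/carryover flags, and detected in
≥ `min_detected` (default 2) experiments. With the default, a site
detected in exactly two experiments additionally needs sub-threshold
signal in ≥ 1 further experiment (waived when it is detected in every
experiment there is). This formalizes, rather than reproduces verbatim,
the narrative admission rule used in curated studies where a 2/6-detected
site was kept on the strength of 3–8% sub-threshold signal elsewhere.

## The synthetic-data generator

Simulation is pileup-level: the pipeline consumes per-strand counts, so
read-level simulation would add nothing testable (a thin paired-end SAM
emitter exists solely to exercise the converter). Defaults model a
three-plant, two-strategy (total RNA and rRNA-depleted) strand-specific
leaf RNA-seq design:

| parameter | default | meaning |
|---|---|---|
| `genome_length`, `n_genes` | 30 kb, 8 | ≥ 1 multi-exon CDS, 1 rRNA locus, both strands |
| `coverage` | total 500×, rRNA-depleted 500×, mRNA 8× | mean coding-strand depth per strategy; poly(A) depth ~1.6% of total, mirroring the poor plastid retention of poly(A) selection |
| `rrna_boost` | 20 / 2 / 0.1 | rRNA-locus depth multiplier per strategy |
| `antisense_fraction` | 0.10 | opposite-strand depth relative to coding (pervasive plastid antisense transcription at lower abundance) |
| `n_edit_sites`, `efficiency_range` | 40, [0.15, 0.95] | C→U edits at coding-strand C positions; edited reads ~ Binomial(depth, e) |
| `carryover_rate` ρ | 1/100 | opposite-strand complementary count ~ Binomial(opposite depth, ρ·e); within the observed 1/2840–1/63 envelope |
| `rrna_mod_sites` | 12 sites, rate 0.3 | substitution types drawn from a 12-type spectrum in which C→T is ~6%, biased 80/20 to the noncoding strand |
| `junction_artifact` | window 6 bp, rate 0.15 | mismatches planted on the exon side of intron boundaries |
| `base_error` ε | 10⁻³ | uniform over the three alternative bases |

Depth is Poisson around the strategy mean (no overdispersion — adequate for
desk-scale testing); introns receive 30% of exon depth (pre-mRNA);
intergenic background 2%. Auto-placed edits keep ≥ 2 × junction-window
distance from intron boundaries, because a planted edit inside the
junction window would be operationally indistinguishable from a junction
artifact and truth classes are mutually exclusive by contract. All draws
flow from explicit integer seed streams; a fixed seed reproduces outputs
byte-identically.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: position-dependent coverage along transcripts,
PCR duplicates and mappability structure, overdispersed depth,
quality-correlated error profiles, genomic SNPs/paralog leakage
(nuclear/mitochondrial plastid-like copies are out of scope, as is the
BLAST check used against them), and real rRNA modification chemistry (the
spectrum is a phenomenological multinomial).

## Numerical choices and degenerate inputs

- Thresholds are compared with ≥/≤ so boundary cases are deterministic:
  exactly 3 reads at VAF exactly 0.10 is called.
- Zero depth yields efficiency 0.0; zero opposite reads yield discordance
  0.0.
- Multi-allelic records report the major alternative only, flagged
  `multi_allelic` (a second non-reference base at ≥ 3 reads).
- N reference positions yield no calls; reads with N bases are not counted.
- Duplicate pileup keys, negative counts, unknown strands, coordinates
  beyond the genome, and ungapped-alignment/genome mismatches are hard
  errors rather than warnings.
- CDS features whose spliced length is not a multiple of 3 are kept with a
  warning flag; explicit GFF3 UTR records are honored but UTRs are never
  inferred.

## Problem sizes

The shipped tests and the acceptance script run the generator at a 30 kb
genome, 8 genes, 6 experiments, depth 500 (≈ 360 k pileup records,
seconds per run), chosen as the smallest configuration that exercises all
artifact channels at realistic per-site read counts. Efficiency
calibration uses depth 10⁴ with 200 replicates per level; the curated-set
replication is exact and instantaneous.

## Known limitations

- Carryover shadows that leave zero opposite-strand reads in every
  experiment are undetectable in principle; the tests therefore assert
  flagging for every shadow with observed signal.
- The 2-of-N corroboration rule is this package's formalization of a
  narrative criterion; `min_detected` and the corroboration switch are
  exposed so users can tighten or relax it.
- rRNA exclusion is wholesale; genuinely edited rRNA positions (if any)
  are sacrificed for specificity, matching conservative curation practice.
- Coordinate harmonization assumes the multiple alignment is correct; it
  is validated only for sequence identity, not alignment quality.
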
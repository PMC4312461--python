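# Methods

`paleovar` is a self-seeding simulation pipeline for measuring how
post-mortem DNA damage, read length, GC content, reference divergence and
coverage depth affect short-read mapping and diploid variant calling. Every
stage is written against an explicit truth ledger, so the effect of each
treatment can be measured exactly rather than estimated.

## Genome-pair simulation

A reference sequence and a diploid sample (two homologous chromosomes) are
related by the unrooted tree `(reference:1x,(chr1:0.5x,chr2:0.5x):0.5x)`.
HKY is time-reversible, so the root is pulled onto the reference tip: the
reference is drawn i.i.d. from the stationary distribution
(π_G = π_C = GC/2), evolved along a shared branch of 1.5x to the
bifurcation, then along two independent 0.5x terminal branches. Events on
the shared path are homozygous, events on a terminal branch heterozygous;
the expected hom:het event ratio is therefore 1.5:1 before coincident-site
effects.

Substitutions use closed-form HKY transition probabilities per branch
(κ = 2, four discrete-gamma rate categories with shape 1.0 by quantile
midpoints renormalised to mean one, 10% invariant sites), which collapses
multiple hits within a branch — the same information an alignment of the
end-point sequences exposes. Indel lengths follow P(k) ∝ k^-1.7 truncated
at 5 bp; the indel event rate is the substitution rate divided by the mean
indel length (≈1.715 bp) so that indel-affected and SNP-affected position
counts are approximately equal. Note the realized mean indel length is
reported as-is (~1.7 bp); we do not target any other value. Indel events
are placed uniformly, applied in branch order (shared, chr1, chr2), and an
event overlapping an earlier event's footprint (±1 bp pad) is discarded —
a rare occurrence that keeps the truth catalog composable. Insertions on
the shared branch continue to evolve along each terminal branch; when the
two descendant copies differ, two heterozygous insertion records are
emitted.

Chromosome sequences are **constructed by replaying the truth catalog**
against the reference, making the catalog exact by construction (the
replay invariant is also asserted in tests). Truth indels keep their raw
placement; canonical left-aligned placement is recomputed against the
reference wherever positions are compared.

Branch lengths are calibrated by bisection (on a fixed internal seed,
400 kb genomes, 5% relative tolerance) so the realized density of
variant-affected positions matches ~2.6/kb ("low", ≈0.3% divergence) or
~29/kb ("high", ≈3%); the calibration is cached per (GC, divergence).

## Read synthesis and trimming

Raw pools are 100 bp single-end reads drawn uniformly from both strands of
both chromosomes at deep per-chromosome coverage, with a uniform per-base
substitution error model at constant Phred Q35 (ε ≈ 3.2·10⁻⁴). This keeps
the sequencing-error ledger exact; it does not reproduce any particular
instrument's position-dependent quality profile. Reads are trimmed from
the 3' end (the only physically coherent truncation for a 5'→3' sequenced
read) to exponential length distributions: 15% of reads at the mean
(40/60/80 bp), decreasing 25% per bp, truncated at mean ± 10 bp and
renormalised.

## Damage model

Fragmentation bias acts at read selection. A trimmed read is accepted with
probability `0.5 · w5(b5) · w3(b3) / max(w5)·max(w3)`, where b5/b3 are the
genomic bases immediately 5' of the fragment start and 3' of its end on
the source strand. Weight tables (per level, config-overridable):

|        | 5' G | 5' A | 5' T | 5' C |  (3' side is the pyrimidine mirror) |
|--------|------|------|------|------|--------------------------------------|
| low    | 1.2  | 1.1  | 0.9  | 0.8  |                                      |
| high   | 1.6  | 1.3  | 0.7  | 0.4  |                                      |

Each table averages 1.0 at equal base frequencies, preserves the ~2:1 G:A
(and C:T) excess, and reproduces purine enrichment of ~+20%/+10% (low) or
~+60%/+30% (high) immediately 5' of accepted fragments. The no-damage
level accepts at a flat 0.5.

Deamination converts terminal C→T from the 5' end and G→A from the 3' end
with probability p0 · 0.75^offset until it falls below 0.01: p0 = 0.12
(low, 9 eligible positions per end) or 0.4 (high, 13 positions). The two
tracks act on different template bases, so on very short reads they
overlap without conflict. Damage applies to the read as sequenced,
layered on top of any sequencing error, and every edit is ledgered.

Coverage depth is accounted pre-mapping: reads are drawn without
replacement until drawn bases ≥ depth × haploid reference length.

## Mapper

Seed-and-extend with exact 13-mers at seven evenly spaced offsets per
strand (on a 40 bp read no two edits can break all seven seeds, keeping
the search near-exhaustive within budget). Candidate loci are scored by
infix edit-distance alignment (edlib) of the whole read against a
band-padded window (band 6). The mapper emulates the BWA-`aln` contract
class rather than a modern sensitive aligner:

- mismatch budget `ceil(0.05 · read_len)` (2/3/4 edits at 40/60/80 bp);
- gaps cost their length plus a per-gap opening surcharge of 1;
- gap runs longer than 1 bp are rejected outright (the k-difference
  default of that aligner family disables gap extensions), configurable
  via `max_gap_len`;
- an ungapped (Hamming) placement is preferred whenever it costs no more
  than the gapped path, so adjacent substitutions are never rendered as
  I/D pairs;
- a best score tied between distinct loci → the read is discarded
  (multi-mapper policy); mapping quality is a best/second-best gap
  heuristic capped at 60.

These settings make 2–5 bp indels unmappable by design — reads spanning
them either exceed the weighted budget or carry an over-long gap — which
is the dominant mechanism limiting indel recovery, as in the emulated
pipeline. `max_mismatch_frac` is deliberately exposed: raising it toward
0.08 recovers several percent of high-divergence mapping at the cost of
more damage-carrying reads in pileups.

## Caller

Per-column diploid genotype likelihoods over {ref-hom, het, alt-hom} with
per-base error from the (constant) pool quality capped at Phred 40, weak
non-reference priors (het 10⁻³, alt-hom 5·10⁻⁴), and a MAQ-family
error-dependency discount: the i-th base contradicting a genotype
contributes ε^(0.7^i) rather than ε. Without this device, stacked
terminal deaminations (several reads damaged at the same site) produce
confident false heterozygotes at rates far beyond anything the emulated
caller family exhibits; 0.7 makes a damage pileup need ≥5 concordant
reads at 16× to out-vote the reference. Call quality is the Phred-scaled
posterior of the reference-homozygote; QUAL values are capped at 3000.

Indels are called from left-aligned I/D observations with the same
likelihood machinery on support counts (indel error 10⁻⁴, same dependency
discount). Observations within 5 bp of a read end are ignored as
alignment-ambiguous, and the opportunity count is the number of reads
spanning the site with ≥5 aligned bases on each side. Calls are filtered
at QUAL ≥ 20 and depth 1–30 (the standard first-pass quality filter of that pipeline family);
no duplicate marking, no recalibration.

## Evaluation

SNPs are counted in allele copies (hom = 2, het = 1, on both the truth
and the called side): a copy is correct only if position and alternate
base both match, so a truth het called as hom yields one correct copy
plus one spurious incorrect copy. SNPs within 5 bp of any truth or
called indel are excluded from both sets; only positions inside the
500 bp edge margins are scored. Indels are scored at event level by
left-aligned position within ±3 bp — a matched pair is one correct call
regardless of genotype — under a one-to-one maximum-cardinality,
minimum-total-distance assignment (solved exactly per window-connected
cluster). Accuracy = correct/called; completeness = correct/truth; the
hom:het ratio-of-ratios divides the called hom:het ratio among correct
events by the truth ratio (1 = unbiased zygosity recovery).

## Experiment grid and regressions

`run_grid` walks GC × divergence × read length × damage × depth ×
replicates with named RNG substreams per stage, so any cell is
independently reproducible from the master seed. Within one (pair, read
length, damage) series the deepest accepted pool is mapped once and
shallower depths are nested random prefixes of it — read order is random,
so subsampling before or after mapping is statistically equivalent and
each read is aligned exactly once. Failed cells are flagged and the run
continues. Replicate pools are averaged per cell (mean of ratios, sd
retained). Regressions are OLS with intercept on (GC%, read length,
damage coded 1/2/3, depth in ×), fitted separately per divergence level,
with an optional log(depth) form; slope comparisons between divergence
levels use an interaction-term fit.

## Problem sizes

The full-scale design (10,001,000 bp pairs, 300× raw pools, 1134 pools)
is supported by configuration but the package's default reduced design
uses ~0.1–1 Mb genomes and one replicate pair per GC × divergence. The
acceptance script runs 120 kb genomes across all 54 treatment series and
seven depths; the test suite runs a 100 kb single-GC slice. At these
sizes the completeness and accuracy averages carry sampling noise of a
few percentage points, which is inside the comparison tolerances used.

## What the generator does and does not emulate

The synthetic data reproduce the stated damage mechanisms exactly —
selection-level fragmentation bias, exponential positional deamination,
exponential trim-length mixtures — and the genome model's divergence
densities. They do not emulate: instrument-specific quality profiles
(errors are uniform Q35), adapter or paired-end artifacts, library
preparation chemistry (no nicks, overhangs or UDG treatment), reference
alignment errors in the truth (truth is recorded directly, not inferred
by re-aligning the genome pair), or any particular aligner binary's
heuristics beyond the contract described above. Consequences observed at
reduced scale: the percent of reads mapped is nearly flat in read length
at low divergence (the strong length attrition reported from ART/BWA stacks
appears to stem from instrument-profile and aligner-version specifics),
and completeness values run somewhat higher than with re-aligned truth,
which inflates the truth denominator. Passing tests therefore validate
the mechanisms and their interactions, not instrument- or
binary-specific magnitudes.

## Known limitations

- Unit-cost alignment with post-hoc gap surcharges approximates, but is
  not identical to, affine-gap DP; rare tie-break differences slip
  through (documented tolerance in the mapper-vs-oracle property).
- The caller's dependency discount is a scalar device, not a learned
  error covariance; its value (0.7) is a design constant.
- hom:het ratio-of-ratios can dip slightly below 1 at the highest depth:
  homozygous variants cluster on the shared branch, and variant-dense
  regions lose coverage to mapping attrition before heterozygous-carrying
  regions do.
- Single-contig genomes only; no N bases; diploid samples only.
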
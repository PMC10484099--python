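# Methods

This note documents the models, parameter choices and numerical
conventions behind `methpanel`, and what the synthetic validation does and
does not demonstrate about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open; β values are fractions in
[0, 1]. Conversions happen only at I/O boundaries: BED stays 0-based, the
Bismark coverage dialect (`.cov`) is written 1-based inclusive with a
0–100 methylation percentage recomputed from the counts (which makes a
write→read→write cycle byte-stable), and VCF is 1-based via pysam.

## Panel design

**Tiling.** Probes of fixed length L (default 120 nt) are placed
left-to-right with step = round(L/k) for tiling density k, and the
terminal probe of each region is right-aligned to the region end. This
guarantees every target base is covered and the mean per-base probe depth
is ≈ k for regions much longer than L (the suite checks ±0.5). Regions
shorter than L — promoter-sized targets of 100–200 bp — receive one probe
centered on the region, extended into the flanks and clipped at
chromosome bounds; flank extension is what makes near-target capture
observable downstream. Probes containing any N are dropped (they could
not be synthesized) rather than repaired.

**Consensus masking.** Multiple masker tracks are combined before probe
filtering. The "least stringent" policy masks a base only when *every*
masker flags it (set intersection), maximizing retained probes; "most
stringent" is the union. A probe is rejected when its masked-base
fraction strictly exceeds `max_masked_fraction` (default 0.25); the
tolerance keeps coverage at repeat edges. The specific rejection
threshold is a design choice of this package — capture vendors do not
publish one — and is exposed as a parameter.

**GC boosting.** Capture efficiency drops for GC-rich fragments, so
probes are replicated ("boosted") by GC content. The default schedule is
a doubling ladder — GC ≤ 0.60 → 1 copy, (0.60, 0.65] → 2, (0.65, 0.70] →
4, (0.70, 0.75] → 8, above → 16 — monotone in GC and capped at 16. Any
monotone schedule can be supplied; non-monotone schedules are rejected.

**In-silico coverage** is the fraction of target bases under the
*deduplicated* probe footprint; boosting never changes it (copy numbers
affect capture probability, not footprint). Panel accounting reports both
distinct probe placements and synthesized oligos (Σ copy numbers), since
vendor probe counts may mean either.

## The simulator

The generator emulates the study system so each analysis stage can be
validated against known truth without external data.

**Reference.** A first-order Markov chain over {A,C,G,T} whose transition
matrix is constructed to hit a target GC fraction (default 0.45) and CpG
dinucleotide rate (default 0.02, i.e. CpG-depleted relative to GC²/4 as
in mammalian genomes): P(G|C) is set to cpg_rate/π_C and the remaining
rows are rescaled to preserve the stationary mass of G. Feasibility
requires P(G|C) ≤ 0.95. At ≥50 kb the realized GC is within ±0.02 and
the CpG rate within ±20% of target. Optional planted features: tandem
repeats (recorded as a mask track) and a diverged segmental copy
(pseudogene/paralog stand-in).

**Diploid truth.** SNVs are placed by per-base Bernoulli sampling at
`snv_rate` (default 10⁻³), multiplied inside a declared variant-dense
region (default 4–5×) to emulate a hyperpolymorphic locus; each variant
is heterozygous with probability 0.8 (assigned to one haplotype) or
homozygous-alternate, with a 2:1 transition:transversion ratio.

**Methylation truth.** Each reference CpG draws a β per condition from a
bimodal Beta mixture (default: equal weights of Beta(1,9) and Beta(9,1)),
reflecting the empirical bimodality of CpG methylation. Differential
regions are planted by adding a signed delta in condition B. Baseline
βs inside planted intervals are redrawn from a Beta oriented away from
the saturating boundary (default Beta(2,5) for gains — hypomethylated
baselines, as for stimulus-responsive promoters): without this, a +0.3
delta planted on a CpG at β = 0.95 would clip to a 0.05 effect and the
truth label would misstate the planted effect size. The plain
shift-and-clip semantics remain available (`dmr_baseline_shape=None`).

**Capture and chemistry.** Fragment starts are uniform; insert sizes are
Normal(250, 30) truncated to [read length, 500], echoing ~250 bp
fragmentation. A fragment is retained with probability
min(1, 0.1 × Σ copy numbers of overlapping probes) — the simplest model
in which boosting is observable in coverage — and off-target fragments
pass at `off_target_rate` (default 0.01), which yields ≥10-fold on-target
enrichment. Each fragment derives from one uniformly chosen haplotype and
one conversion strand (directional protocol: OT reads interrogate
plus-strand cytosines, OB minus-strand). Per-molecule CpG methylation is
Bernoulli(β); conversion turns unmethylated Cs into Ts except with
probability `failure_rate` (BS default 0.015, EM default 0.006, matching
typical residual non-CpG methylation of ~1.5% and ~0.6%), and converts
methylated Cs with probability `overconversion_rate` (default 0.005, a
stand-in — libraries rarely report it). Sequencing errors are i.i.d.
substitutions (default 10⁻³). Reads carry their true origin, so
downstream modules are tested without an aligner; paired FASTQ is still
emitted for external pipelines. PCR duplicates, per-cycle quality
profiles and adapter read-through are not modeled — passing tests say
nothing about deduplication or alignment artifacts on real data.

## Methylation quantification

A directional-protocol rule is enforced throughout: a read contributes to
a cytosine only if its conversion strand interrogates it (OT → reference
C positions, read C = methylated / T = unmethylated; OB → reference G
positions, G/A). Other read bases at those positions are genetic
mismatches and are ignored for methylation. Context (CpG/CHG/CHH) comes
from the reference trinucleotide, never from reads. Overlapping mates are
deduplicated so each molecule counts once per position (mate 1 kept
whole, mate 2 clipped to the uncovered remainder).

Strand merging sums the counts of the two symmetric cytosines of a CpG
and reports the unit at the plus-strand C coordinate; records whose
claimed CpG context contradicts the reference raise an error. The
coverage filter keeps units with depth ≥ `min_cov` (inclusive ≥, the
common reading of a "10X filter") and is idempotent.

Conversion efficiency is estimated from non-CpG cytosines, where true
methylation is ~0 in most somatic cells: the pooled CHG+CHH methylated
fraction estimates the conversion-failure rate directly (pooled is
primary; per-context values are reported alongside). Note the estimate
includes a small sequencing-error floor (~e/3).

## Differential methylation

The DMP rule is a fixed effect-size threshold, not a statistical test —
no multiple-testing correction applies, and this is deliberate: Δβ =
β_A − β_B over CpGs covered in both samples, DMP iff |Δβ| strictly
exceeds 0.1 (a difference of exactly 0.10 is not a DMP). DMRs are maximal
runs of ≥2 consecutive same-direction DMPs, where "consecutive" means
adjacent in the shared-CpG list (a covered non-DMP CpG breaks the run; a
direction flip starts a new run). No base-pair gap limit applies by
default — sparse panels can have large gaps between adjacent covered
CpGs — but `max_gap` is available. The cross-chemistry consensus keeps
CpGs with |Δ| > 0.10 in one chemistry, |Δ| ≥ 0.05 in the other, and equal
signs, annotating which method cleared the primary bar.

Nearest-feature annotation: a feature containing the CpG wins with
distance 0 (smallest id among containers); otherwise the feature with the
nearest midpoint. Exact midpoint ties go to the lexicographically
smallest id and are flagged. The containment-first rule exists because a
CpG inside a long feature can be nearer to a short neighbor's midpoint,
and "inside" should always report distance 0.

## Genotyping

Per site, counts of informative read bases feed a 10-genotype likelihood:
P(b|allele) = 1−e for a match, e/3 otherwise; a heterozygote emits each
allele at 1/2; genotypes are scored under a flat prior and the argmax is
called with GQ = −10·log₁₀(1 − posterior), capped at 99. Sites with
informative depth < `min_depth` (default 30) are not called — a no-call
keeps replicate-overlap statistics well defined. Only SNVs are modeled.
Mate overlaps count once. This is an explicit, minimal model rather than
a reimplementation of any production caller's heuristics (no BAQ, no
quality recalibration).

In bisulfite-aware mode, read bases that conversion can explain are
excluded from the informative set: C/T on OT reads (a T may be a
converted C) and G/A on OB reads. At a C/T SNP covered only by OT reads
every base is excluded; such sites are reported as conversion-ambiguous
no-calls rather than risked calls. The suite verifies this eliminates
all spurious C>T/G>A calls at unmethylated CpGs while leaving
non-confounded SNV recovery at the unconverted-library rate.

Replicate overlap counts variants (non-reference genotypes) identical in
chromosome, position, alternate alleles and zygosity, reported as a
shared count and per-sample fractions.

## Reporting

Region summaries give per-region median/min/max depth and the fraction of
bases at each of 10/20/30/50/100X (monotone by construction). A region
counts as "captured" when ≥1 base reaches the 10X filter — published
capture reports rarely define this rule, so it is an explicit documented
choice here. Flank coverage is the fraction of bases in (region ± w) \
region at or above a depth threshold; w = 0 is reported as NaN. β
concordance is Spearman's ρ with average ranks for ties
(scipy.stats.spearmanr) over shared CpGs, optionally restricted to
regions.

## Validation scales and determinism

The test suite and `scripts/acceptance.py` run on 60–200 kb toy genomes
with 20k–180k proposed fragments per library (footprint depths of roughly
40–200X) — sizes chosen so the whole study, including six libraries,
completes in well under a minute while leaving every statistic far from
its small-sample regime. All randomness flows through
`numpy.random.default_rng` seeds; identical seeds reproduce byte-identical
outputs. β-recovery checks exclude CpGs overlapping planted variants,
because a C/T SNP inside a CpG legitimately shifts apparent methylation
(genetics, not estimator noise); uniform depth for the binomial-bound
check is obtained by hypergeometric downsampling to exactly 100 calls.

## Known limitations

- No alignment stage: real-data use delegates mapping/deduplication to
  external tools and starts from their outputs (observation tables or
  Bismark coverage files).
- Capture retention is linear in summed probe copy number with
  saturation; real hybridization kinetics (GC dependence of capture
  itself, probe cross-hybridization, melting behavior) are not modeled,
  so boosting benefits are qualitative.
- Non-CpG methylation defaults to zero; tissues with genuine CHH/CHG
  methylation would bias the conversion QC upward.
- The DMP/DMR caller implements the fixed-threshold rule only; it makes
  no claim of statistical error control.
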
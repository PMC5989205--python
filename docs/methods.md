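# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `hapdose`, and the limits of what its synthetic data can show.

## 1. Synthetic linked-read generator (`hapdose.simulate`)

**What it emulates.** Targeted linked-read sequencing of a carrier mother's
~2.2 Mb chrX locus, followed by shallow plasma sequencing of het SNPs. The
default region holds 850 informative heterozygous SNPs (the middle of the
700–1,000 range typical for this locus) placed uniformly at random; every
informative SNP is heterozygous, so haplotype 2 is the complement of
haplotype 1.

**Molecules and gems.** Input molecules have exponential lengths with mean
`molecule_mean_len` = 52,700 bp (only the average is characteristic of the
library; the exponential is the standard fragment-length model) and are
placed uniformly. Each molecule is sequenced sparsely: at every covered SNP
the number of read observations is Poisson(`molecule_read_depth`), default
0.2× per base — the linked-read signature of many molecules each sampled
shallowly. The spec of the regime fixes total coverage, not molecule count,
so the generator derives the molecule count per haplotype as

    N_hap = target_coverage · L_hap / (2 · molecule_mean_len · molecule_read_depth),

giving ~676× observation depth at the default `target_coverage` = 676.
Molecules are then shuffled into gems of `molecules_per_gem` = 10; gems may
mix haplotypes, which is what forces the phasing stage to resolve
per-molecule rather than per-barcode identity. Observation alleles are
flipped with probability `seq_error_rate` (default 10⁻³).

**Structural mutations are geometric.** The mutant haplotype gets its own
coordinate space: a deletion excises the interval (interior SNPs vanish
from that haplotype and molecules genuinely span the breakpoint, as they
would against a deletion-bearing chromosome); a tandem duplication repeats
the interval, so each interior SNP exists in two copies and is observed at
doubled rate — producing the 2:1 (≈ 2/3 vs 1/3) allele-fraction signature.
A point mutation additionally emits mutant/wild-type observations at its
own site from molecules covering it.

**Plasma model.** Fetal fraction *f* is defined on autosomal genome
equivalents. The mother contributes two X copies per genome equivalent and
the male fetus one, so the fetal share of chrX reads is φ = f/(2 − f).
With the fetal allele at SNP i equal to the transmitted haplotype's allele
(flipped across each configured crossover), per-SNP depths are

    a_i ~ Binomial(depth_per_snp, (1 − φ)/2 + φ·1[fetal allele = hap1 allele]),

with `depth_per_snp` = 200, the depth recommended for confident RHDO at
~1,000 SNPs. Depths sum exactly to `depth_per_snp`. The fetal SV's own
effect on plasma depth inside the mutated interval is not modeled: the
mixture formula treats every SNP identically, which overstates the fetal
signal at the handful of interior SNPs of a transmitted deletion. At the
default regime this shifts the pooled fraction by well under one part in
10³ and is ignored.

**What this does not show.** No base-level reads, no alignment or mapping
ambiguity, no GC or capture bias, no PCR duplicates, no maternal
mosaicism, uniform rather than LD-structured SNP spacing, and plasma depth
exactly constant per SNP. Tests passing on this generator demonstrate the
*algorithms* under the stated statistical regime, not robustness to
real-data artifacts.

## 2. Phasing (`hapdose.phasing`)

Per barcode and SNP, observations are tallied and the majority allele
taken (ties discarded — no guessing); barcodes observing fewer than two
distinct SNPs are dropped. Every pair of majority-called SNPs within a
barcode votes *cis* (equal alleles) or *trans* (opposite). Pairs farther
apart than `max_pair_bp` (default 4 molecule lengths) are skipped: at that
distance co-barcoded observations come from different molecules of the gem
and their relative phase is random, so the cap removes pure noise and
quadratic work.

Edges survive with `max(cis, trans) ≥ min_support` (default 2 — one
chimeric gem can never set an edge) and majority ratio ≥ `min_ratio`
(default 0.75). Connected components become phase blocks. Relative phase is
propagated over a maximum-support spanning tree (Kruskal; ties broken by
lower SNP indices, so the result is deterministic), then refined by
deterministic single-SNP flips that greedily increase the per-barcode
maximum-agreement objective Σ_b max(m_b, k_b − m_b). The refinement is a
no-op on consistent data and corrects the occasional tree-propagation error
near weakly connected SNPs; on small instances it reaches the enumeration
optimum (property-tested). Kept non-tree edges contradicting the final
assignment are counted as conflicts; a block with > 5% conflicting
non-tree edges is flagged low-confidence.

**Anchoring.** Mutation-supporting barcodes are those whose majority
observation at a point-mutation site is the mutant base, or the
mutant-supporting sets from the SV linkage finders. Each votes for the
block strand its alleles match, restricted to SNPs within
`flank_scale × molecule_mean_len` of the mutation — farther votes would
come from unrelated molecules of the same gem, which are phase-random.
The winning strand becomes HapA, its complement HapB. Blocks with no
direct votes are chained through barcodes shared with anchored blocks;
blocks that remain unanchored are excluded from the HapA/HapB vectors and
from dosage analysis (conservative) and reported.

**Known limitation.** With multi-molecule gems, two haplotypes can share a
gem and overlap the same SNP; the per-barcode majority is then only
statistically informative. Exact truth recovery is therefore guaranteed
only for haplotype-pure barcodes (one molecule per gem, error-free) — the
regime in which the exactness property is tested — while the default
mixed-gem regime achieves ~99–100% concordance empirically.

## 3. SV-to-haplotype linkage (`hapdose.sv_linkage`)

**Deletion.** Barcodes with observations inside the deleted interval carry
the wild-type haplotype. Candidate mutant barcodes observe both flanks
within `flank_scale × molecule_mean_len` (default 1.5×, tying the window
to molecule scale) of the breakpoints and nothing inside. Because the
generator consumes allele observations rather than raw bases, the
re-alignment of mutant reads to a deletion reference is realized as its
allele-space equivalent: a candidate's 5′- and 3′-flank majority alleles
must phase to the *same* haplotype across the gap; inconsistent candidates
(e.g. gems whose two flanks come from different molecules) are excluded.
The majority side of the consistent barcodes sets the linkage, and the
flank check passes when both flanks' aggregate votes favor the same
haplotype. With deep physical coverage the vote margin is wide (~86:14 at
the study regime) even though independent flank molecules contaminate the
candidate set.

**Duplication.** Pooled allele fractions are computed at interior SNPs;
those outside [`af_low`, `af_high`] = [0.4, 0.6] are divergent. At 600×
the per-SNP false-positive probability of these bounds on balanced data is
≪ 1%, while true 2/3 : 1/3 signals pass with overwhelming power. The
over-represented allele marks the duplicated haplotype; gems carrying it
at divergent SNPs are mutant-supporting. A majority vote across divergent
SNPs sets the linkage; a vote below 75% flags low confidence.

## 4. Changepoint detection (`hapdose.changepoint`)

Change-in-mean segmentation under Gaussian noise: segment cost is the
residual sum of squares divided by a robust global noise variance, plus an
MBIC-style penalty β = 3·log n per changepoint (three effective parameters
per extra segment: mean, location, and the segment-count term). The noise
sd is estimated as median(|Δx|)/(√2·0.6745) — first differences are immune
to a small number of mean shifts. The sd is floored at 10⁻⁴ of the data
scale so that noise-free piecewise-constant input segments cleanly instead
of chasing prefix-sum cancellation dust. Minimum segment length defaults
to 10 SNPs to suppress spurious short segments.

Two solvers share this one objective: PELT (pruned; the SSE cost is
subadditive, so pruning is lossless) and the unpruned O(n²) optimal
partitioning DP. Their exact agreement on every series is a tested
property; tiny series are additionally checked against full enumeration of
all segmentations. Zero breakpoints is a legal result.

## 5. Dosage analysis (`hapdose.rhdo`)

The HapA fraction series F_i = a_i/(a_i+b_i) is screened once with a
3σ individuals-chart rule (mean and sample sd of the retained set; the
single pass mirrors a Shewhart chart and guards the changepoint stage
against spikes from duplicated/repetitive sequence). A changepoint is
confirmed as a fetal recombination only if its flanking segment means lie
on *opposite* sides of 0.5 (same-side shifts are drift) **and** a
two-sample z-test on the pooled flanking counts rejects equality at α
(default 0.01). Confirmed crossovers reflect the series (a and b swap) on
every segment an odd number of crossovers away from the anchor segment —
the spec-default anchor is the first SNP; the pipeline anchors at the SNP
nearest the mutation so the call always refers to the mutation locus (for
the built-in five-family design both conventions coincide). The
adjustment is idempotent.

The genotype call pools all retained counts and applies a two-sided exact
binomial test against 0.5 at α = 0.01; "inconclusive" is an explicit
outcome, so at f = 0 the caller stays silent in ≥ 99% of draws
(empirically 991/1000 at the study regime — the exact test's discreteness
keeps the true rate just above 99%). Fetal fraction is estimated by
inverting the chrX dosage relation, f̂ = 2φ̂/(1+φ̂) with φ̂ = |2F̄ − 1|; the
mixture formula for φ is the generator's own declared convention, so the
estimator's recovery of truth (±0.5 percentage points in the mean over 20
draws at both printed extremes) verifies internal consistency, not an
externally validated fetal-fraction assay. A percentile bootstrap over
SNPs (200 resamples) supplies the CI. The estimator's absolute value makes
it non-negative, a bias that matters only as f → 0.

## 6. Orchestration, determinism, problem sizes

One master seed fans out to per-stage seeds via BLAKE2b hashing of
"seed:stage-label", so any stage can be reproduced in isolation and
identical config + seed yield byte-identical JSON reports (hashes of the
config are embedded as provenance). The built-in five-family design uses
the printed per-draw fetal fractions, 850 SNPs, 200× plasma depth, 676×
maternal coverage and a single mid-region crossover in family 5; mutation
intervals are plausible synthetic stand-ins for the quoted exon ranges
(the gene is minus-strand, so early exons sit at high coordinates). The
test suite scales property checks down (e.g. a 0.5 Mb/120-SNP region for
phasing and SV properties, n ≤ 200 for solver-equivalence checks) while
the acceptance run keeps the full study regime; the chosen sizes keep the
whole suite at a few minutes on one CPU.

## 7. Open design choices made here

- Barcode-level (not molecule-level) SV evidence, as barcodes are what is
  observable; contamination by coincidental flank molecules is tolerated
  through voting rather than filtered by molecule reconstruction.
- Unanchored blocks are excluded from dosage rather than guessed.
- Draws of one family are analyzed independently (two draws of the
  crossover family each detect their own changepoint).
- The phase-graph distance cap, anchor vote window and deletion flank
  window all scale with molecule length rather than being fixed base-pair
  constants.
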
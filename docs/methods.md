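# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would want to know about.

## Nascent-transcription model and the conversion-count generator

Metabolic labeling marks transcripts made during the labeling window; reads
from *new* transcripts carry nucleotide conversions at a high per-site rate,
reads from *old* transcripts only at the sequencing-error background. With
`n_T` convertible sites per read (fixed at 20), the per-read probability of
carrying at least one conversion is `q = 1 − (1 − rate)^n_T`, so the labeled
fraction of a gene's reads is the mixture `f·q_new + (1−f)·q_old` with `f`
the new-RNA fraction. Because the binomial likelihood is monotone in that
mixture weight, the MLE of `f` is the method-of-moments expression
`(labeled/total − q_old)/(q_new − q_old)` clamped to [0, 1]; the test suite
verifies this against a brute-force likelihood grid at step 1e-4.

The generator draws per-gene baseline means from a log-normal
(`log_mu = 7.0`, `sigma = 1.0`; a median of ~1100 total reads per gene,
matching tens of millions of reads spread over ~10k expressed genes), total
counts as gamma-Poisson (NB) with dispersion 0.1, and labeled counts as
binomial thinning with the mixture probability. The baseline new fraction is
0.5 — a 4 h labeling window against typical ~4 h mRNA half-lives turns over
about half the pool. Conversion and background rates default to 0.03/site
and 0.001/site (`q_new ≈ 0.46`, `q_old ≈ 0.02`).

Planted classes and their time profiles (log2 relative nascent rate at
4 h / 24 h): rescued −2 / 0, redundant −2 / −2, induced 0 / +1.5, unchanged
0 / 0; default proportions 0.10 / 0.20 / 0.10 / 0.60. Three replicates per
timepoint at 0/4/24 h. Note an intrinsic property of the labeling readout:
background conversions dilute the observed labeled-count fold change (a −2
planted rate change appears as ≈ −1.7 in labeled counts). The classifier
thresholds operate on the observed scale, so this dilution costs a little
sensitivity but no bias in the calls.

## Size factors and the differential test

Size factors are median-of-ratios. For labeling data they are computed on
**total** counts and applied to labeled counts: totals are approximately
steady-state over these timescales, whereas median-of-ratios directly on
labeled counts is composition-biased when a large fraction of genes changes
nascent rate (with 40% perturbed genes we measured a +0.36 log2 shift of
null genes). For plain RNA data the factors come from the tested matrix
itself, selected by the pipeline's `data_type` flag.

The per-gene test is a negative-binomial Wald test on normalized group
means: `lfc = log2((mean_B + 0.5)/(mean_A + 0.5))`, with variance
`[(1/mean_A + α)/n_A + (1/mean_B + α)/n_B]/ln(2)²` by the delta method.
Dispersion `α` is estimated per gene by pooled within-group method of
moments and moderated toward a log-linear mean-dispersion trend. Two
numerical points matter:

* the trend is fit to the log of **binned means** of the unclipped per-gene
  estimates. The log of an individual 4-df estimate is severely
  Jensen-biased low, and clipping negative estimates before averaging biases
  high; bin means of raw values track E[α | mean] almost unbiasedly.
* the default moderation weight is 1.0 (fully trended): with three
  replicates per group a gene-wise estimate carries ~no information, and its
  noise fattens the Wald tails. With the trended dispersion the normal
  reference is calibrated — the null rejection rate at p < 0.05 measures
  0.053–0.056 across seeds. The weight is exposed (`shrink_weight`) for
  datasets where gene-specific dispersion is real and replicates are many.

Genes with mean normalized count below 5 are marked untested (FDR = NA) and
excluded from the BH correction; the pseudocount of 0.5 bounds fold changes
at zero counts.

## Rescue classification

Thresholds (all configurable): α = 0.05, t_down = log2 1.5,
t_recover = log2 1.25, δ_min = 1.0. "Recovered" is the OR of an absolute
floor on lfc₂₄ and a rebound of at least δ_min, because genuinely rescued
genes both return to baseline and overshoot it. Genes significant only at
24 h (down) are *unchanged*, not redundant: redundancy here means an
immediate and sustained dependence on the lost factor. Precedence is
rescued > redundant > induced > unchanged, making the classes mutually
exclusive and exhaustive. Under the default generator, sensitivity for the
rescued class averages 0.92 with empirical FDR ≈ 0.04 over ten seeds.

## Binding generator and region-level analysis

Each gene contributes one promoter-sized region (1 kb), laid out
deterministically over five chromosome labels. Under treatment BRD4 falls by
−1.5 log2 everywhere; p300 rises by +1.0 log2 only at rescued-linked
regions. Replicate signal (two per condition, mirroring typical ChIP
designs) is log-normal with 0.25 log2 SD.

Differential binding depth-scales each sample to signal-per-million before
averaging replicates (no spike-in assumed), then takes
`log2((mean_B + 1)/(mean_A + 1))`. Depth scaling cancels any genome-wide
uniform shift by construction — a global BRD4 exclusion is only visible on
the unscaled signal (`scale="none"`), which is how the generator's planted
−1.5 is checked. Locus-*specific* changes (the p300 gain at 10% of regions)
survive depth scaling essentially intact, which is what the compensation
score consumes. The compensation score `log2fc(gained) − log2fc(lost)` is
antisymmetric by construction; "top 5%" selection ranks the raw per-factor
log2fc, not the score, and truncates at zero so only true gains are
reported.

Cross-model concordance uses the mean-shift statistic (mean B-delta over A's
top sites minus mean over the rest) against `n_perm` random same-size
subsets with add-one correction; permutation p-values are verified uniform
under the null (KS over 200 seeds). Nearest-TSS annotation measures from
the region midpoint, ignores strand, ties break to the lexicographically
smaller gene id, and the default maximum distance of 1 Mb is deliberately
permissive so distal enhancers can attach to their gene.

## Dose matrices and ZIP scoring

The generator builds monotherapy responses from 4PL curves (default bottom
0, top 100, EC50 1, slope 1) over 4 dosages + vehicle per drug (the 5×5 grid
holds the 20 non-vehicle treatment combinations: 16 drug–drug wells plus
4+4 monotherapies), sets every combination well to the Bliss expectation
`yA + yB − yA·yB/100` plus a planted interaction in percentage points plus
Gaussian noise, and clips to [0, 100]. The default doses stay at or below
EC50 so a +20-point planted interaction never clips.

Scoring: monotherapy 4PL fits (bounds bottom ∈ [−5, 20], top ∈ [50, 110],
slope ∈ [0.2, 10], EC50 initialized at the geometric mean of nonzero doses);
for each combination well, two constrained re-fits — along the row with the
bottom pinned to the fitted response of the other drug at that row's dose,
and along the column symmetrically — are averaged to give the observed
potency-shifted response. Delta is observed minus the Bliss expectation of
the fitted monotherapies; the summary is the mean over combination wells and
the most-synergistic-area score is the best 3×3 window mean. Degenerate
flat monotherapies fall back to a flagged constant fit, non-convergent fits
to isotonic interpolation. Calls: > +10 synergistic, < −10 antagonistic.
On noise-free data the null recovers |mean delta| < 1e-14 and a planted +20
recovers 19.9; drug swap changes nothing (symmetry is exact here because
both re-fit families see transposed data).

Scheduling mode is metadata only: the scoring is identical for BETi-first,
concomitant, and p300i-first — any biology of scheduling enters through the
measured matrices, and the package makes no claim about *why* order changes
synergy.

## Resistance course and archetypes

Stage profiles are `baseline + amplitude·template + noise` on a
log-expression scale, with baselines N(5, 1), amplitudes U(1, 2) and stage
noise SD 0.25 by default. Templates over (DMSO, BETi_72h, IC50_r, IC90_r):
evolution (0,1,2,3), degression (3,2,1,0), stress (0,1,0,0), inflammation
(0,0,1,0), interferon (0,1,1,−1). Assignment is by Pearson correlation of
the z-scored profile against z-scored templates (hence invariant to affine
transforms of the profile); below r = 0.5, or on an exact tie, or for a
constant profile, the gene is labeled flat rather than forced.

Clustering is the unsupervised route: Ward linkage on z-scored profiles, cut
at k (k = 2 reproduces a two-module evolution/degression structure, k = 5
the five-module structure). The two routes need not agree gene by gene —
archetypes are interpretations of recurring cluster shapes, and both labels
are reported. Constant-profile genes cannot be z-scored and inherit the
cluster of their nearest non-constant neighbor, flagged with a warning.
Recovery under the default noise: ≥ 99% archetype accuracy and ARI ≈ 0.99
at k = 5.

Gene-set deltas use one-sided Mann–Whitney tests ("set A less down-regulated
than set B") BH-corrected across ordered pairs; sets with fewer than five
matched genes are excluded with a warning.

## Pipeline and reproducibility

Stages run in fixed order, each writing TSV/JSON with a '#' header carrying
the tool version, master seed, and a hash of the analysis-relevant config
(the output directory is excluded from the hash so runs in different
locations compare equal). Every stage draws randomness from a named
substream of the master seed (`SeedSequence([seed, crc32(stage)])`), so
adding or removing a stage never perturbs another stage's draws. Output
files contain no timestamps; the manifest records SHA-256 checksums per file
and reruns with identical config and seed are byte-identical (checked in the
test suite). Coordinates are 0-based half-open everywhere.

## What the synthetic validation does and does not show

The generators plant exactly the structures the statistics look for:
NB counts with a clean log-linear mean-dispersion relationship, log-normal
binding noise, Bliss-plus-constant interactions, and noiseless archetype
templates plus iid stage noise. Passing tests therefore demonstrate
correctness of the estimators and calibration of the tests *under their
assumptions*; they do not demonstrate robustness to batch effects,
mean-dependent labeling efficiency, antibody efficiency differences between
conditions (which break depth scaling), non-Bliss pharmacology, or
correlated gene modules. Problem sizes in the test and acceptance runs
(5000 genes × 9 samples, 1000–2000 regions, 5×5 dose grids, 200-seed
calibrations) were chosen so the full validation completes in well under a
minute while keeping Monte-Carlo error far from each decision boundary.

## Known limitations

* The labeled-count fold change is diluted toward zero by background
  conversions; classification thresholds act on the observed scale. A
  fully model-based alternative (testing estimated new-RNA fractions
  directly) would undo the dilution but needs a variance model for the
  fraction estimate.
* Depth-scaled differential binding cannot see genome-wide uniform shifts;
  with no spike-in this is a property of the normalization, not a bug.
* The ZIP implementation averages row/column re-fits; other implementations
  differ in smoothing details, so scores can differ by a few points on
  noisy matrices (the ±10 call thresholds absorb this).
* Hierarchical clustering at k far from the true module count fragments or
  merges archetypes; k is a config field, not inferred.
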
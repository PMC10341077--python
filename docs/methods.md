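# Methods

## Input model and coordinate conventions

The scoring operates on one sample's allele-specific copy-number profile:
non-overlapping segments per chromosome, each carrying an integer total
copy number C and minor-allele copy number M (M ≤ C − M). This is the
purity/ploidy-resolved product of an upstream tumor-only caller; purity and
ploidy are carried as metadata but do not enter the score, which is defined
entirely on the integer states. The package does not call copy number,
parse BAM/VCF, or infer purity — those are upstream concerns.

Internally all coordinates are 0-based half-open; the segmentation TSV and
the arm-definition TSV are 1-based inclusive on disk and converted at the
I/O boundary only, so interval arithmetic is free of ±1 corrections. UCSC
cytoBand files (already 0-based half-open) are accepted as an alternative
arm source, with the centromere taken as the union of the two `acen` bands.

A genome build contributes chromosome lengths, arm intervals and
per-telomere assembly flags. The centromere belongs to neither arm: any
segment portion overlapping it is excluded from observed territory and from
all numerators. Scored chromosomes default to autosomes 1–22 plus X; Y is
excluded (uninformative for the assay's clinical context and poorly covered
by SNP backbones) but can be included by configuration. The bundled hg19
table uses UCSC chromosome lengths and centromere gap coordinates, with the
acrocentric p telomeres (13, 14, 15, 21, 22) flagged unassembled.

## The observed genome

`observed_genome_bp` is the summed arm-overlapping territory of all
segments. It is the denominator of PLOH and PCNA and the basis of the
evaluability check: profiles observing less than `min_observed_fraction`
(default 0.4) of the assembled reference are unevaluable. The floor is a
package choice — near-empty FFPE profiles would otherwise emit scores from
a handful of segments; 0.4 is low enough to tolerate heavy FFPE dropout yet
high enough that every chromosome can contribute an expected state.

## Component rules

**Expected state.** Per chromosome, the (C, M) pair covering the largest
observed arm territory. Ties break toward smaller C, then smaller M — the
more parsimonious state. A chromosome with no observed territory has no
expected state; it is skipped for PCNA and its telomeres leave the PTCNA
denominator.

**Region construction.** Both PLOH and PCNA work on maximal runs of
flagged territory. A run extends across unobserved gaps of at most
`max_gap_bp` (default 1 Mb — FFPE coverage is patchy, and without fusion
the 10 Mb size filter would be hypersensitive to segment fragmentation); an
observed base of non-flagged state always breaks it. The run's *span*
(including fused gaps) is tested against the size filter; only its
*observed* base pairs enter the numerator — event size and coverage
completeness are kept separate.

* PLOH flags M = 0 regardless of C, so an LOH tract whose total copy
  number steps internally is one region. Homozygous deletions (C = 0)
  count as LOH by default and are flagged in the output
  (`count_homdel_as_loh=False` restores the stricter reading).
* PCNA flags state ≠ expected state, fusing adjacent deviant runs even
  when their deviant states differ (the filter is on altered territory
  size, not uniformity; `fuse_mixed_deviant_states=False` gives the
  conservative alternative).

**Size and whole-arm filters.** Exactly as printed in the defining rules,
with strict inequalities: a region qualifies when span > 10 Mb; a terminal
segment is telomeric when its boundary is < 5 Mb from the chromosome end
and counts only when its span > 1 Mb. "Smaller than a complete chromosome
arm" is operationalized as: a run is a whole-arm event (excluded) when its
observed overlap with an arm reaches `whole_arm_fraction` (default 0.9) of
that arm's observed territory — segmentation never lands exactly on arm
boundaries, so exact matching would never trigger. A run saturating both
arms (a whole chromosome) is excluded by the same per-arm test.

**PTCNA.** For every scored chromosome with an expected state, each
assembled telomere is evaluable when some segment boundary falls inside the
5 Mb window; the outermost such segment anchors the telomere. The telomere
is altered when the anchor spans > 1 Mb, deviates from the expected state,
and the deviation run containing it is not a whole-arm event. PTCNA is the
percentage of altered among evaluable telomeres; with zero evaluable
telomeres the profile is unevaluable. The alteration is required in the
anchoring terminal segment specifically, not merely anywhere inside the
window — the stricter of the two available readings.

**Classification.** GIS = PLOH + PCNA + PTCNA (each in [0, 100], so GIS in
[0, 300]). GI-positive iff GIS ≥ cutoff, default 83. HRD-positive iff
GI-positive and/or pathogenic BRCA1/2; a sample with undefined GIS and no
pathogenic mutation is unevaluable. Unknown BRCA status behaves like
wildtype for the call but is recorded as given. All percentages are
computed in double precision and serialized to 4 decimals.

## Cutoff calibration

`scan_cutoffs` sweeps an integer grid (default 0–300, matching the score's
range) with the prediction convention GIS ≥ c, computes Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) and sensitivity/specificity/PPV/NPV/concordance
per cutoff, and selects the lower end of the first maximal contiguous
kappa-maximizing interval — among equally concordant cutoffs the lowest
classifies the most patients as eligible for therapy. Degenerate input
(single-class reference, duplicated ids) is rejected; unevaluable scores
are dropped and counted. Statistics with empty denominators are reported
as undefined, never as zero.

`min_depth_for_detection(af, k, s)` returns the smallest depth N with
P(X ≥ k) ≥ s for X ~ Binomial(N, af), by exact tail evaluation with
exponential-then-binary search (the tail is monotone in N). It is a
parametric calculator: the alt-read floor and error model behind any
particular published depth threshold are assay-specific, so no fixed
reproduction is attempted.

## Simulator

`simulate_profile` emulates the statistical structure of tumor-only FFPE
segmentation: a diploid-heterozygous baseline (2,1) over all arms,
interstitial LOH tracts (copy-neutral (2,0) or with loss (1,0), 50/50),
interstitial gains (+1 or +2 copies), telomeric gains anchored at assembled
termini, and observation dropout as randomly placed gaps (0.1–5 Mb,
log-uniform). Event sizes are log-uniform on 5–40 Mb by default; placement
is uniform over arm interiors (outside the 5 Mb telomere windows, so the
three event classes map cleanly onto the three components) with rejection
of overlaps and a bounded retry budget. Output is deterministic per seed,
and a ledger records every planted event with its nominal filter verdicts.

What it does not emulate: SNP-level B-allele frequencies, purity mixtures,
subclonality, segmentation error, or correlated (chromothripsis-like)
event clustering. Passing tests therefore demonstrate correctness of the
scoring rules on clean integer profiles, not robustness to caller noise.

Cohort presets: HRD-like (36 LOH / 22 CNA / 26 telomeric events, 10%
dropout; mean GIS ≈ 92 with the low tail crossing the cutoff) and HRP-like
(3/3/2, 10% dropout; mean GIS ≈ 8). `simulate_cohort` additionally draws a
per-sample scar-burden multiplier (lognormal, σ = 0.25, clipped to
[0.5, 1.5]) before Poisson count jitter: real cohorts show continuous
burden heterogeneity rather than two tight clusters, and a classification
threshold is only identifiable from samples that straddle it. Reference
labels are each sample's own GI status, optionally flipped with a
label-noise probability to emulate an imperfect reference assay.

## Problem sizes in tests and the acceptance script

Per-base oracle equivalence uses randomized toy genomes of 2–5 chromosomes
a few hundred to ~1600 bases long, with all size parameters scaled in
proportion — the rules contain no absolute scale, so strict-inequality
behavior is preserved while brute-force painting stays cheap. Threshold
recovery uses 100 replicate cohorts of 60 HRD-like + 40 HRP-like samples
(the larger deficient arm keeps the score density near the cutoff high
enough for the threshold to be identifiable); the clinically shaped
35/96 cohort is used for the zero-noise and integration checks. The
acceptance script mirrors these sizes with 50 recovery replicates and
20 seeds per preset mean.

## Known limitations

* The expected copy number is interpreted allele-specifically (modal
  (C, M) pair), so copy-neutral LOH counts as deviation for PCNA and
  telomere verdicts; a total-CN-only reading would ignore the assay's
  central lesion class.
* Whole-arm exclusion depends on `whole_arm_fraction` when coverage is
  very sparse on an arm, since the comparison is against *observed* arm
  territory.
* The simulator's independence assumptions understate the spatial
  correlation of real scars; simulated kappa values against a noisy
  reference are not comparable to clinical concordance figures.
* One genome build per run; no liftover.
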
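# Methods

## Study design being modelled

The package targets a two-group, fixed-n design: six animals with continued
running-wheel access (RUN) versus six with wheels locked for the final week
(LOCK), perirenal adipose tissue profiled by bulk RNA-seq and quantified as
RPKM, supplemented by adipocyte sizing of three visceral depots and qPCR
validation of selected transcripts against an 18S reference gene. All
statistics are classical: equal-variance Student *t*-tests, Benjamini–
Hochberg FDR, means ± SE.

## Differential-expression cascade

"Expressed in a group" is defined as group-mean RPKM > 0, which for
non-negative data is equivalent to *any* nonzero sample. The strict-zero
reading makes the group-exclusive sets unambiguous: a transcript is RUN-only
only when every LOCK sample is exactly zero. Exclusive transcripts are
excluded from testing (their fold change is undefined) and reported
separately, with no RPKM floor, sorted by mean RPKM descending and ties
broken lexicographically by transcript id for reproducibility.

The per-transcript test is an equal-variance two-sided *t* on raw RPKM.
Testing on the raw scale mirrors the simplest practice for this style of
analysis; a log₂ transform would be defensible but changes which hypothesis
is tested, so it is not applied by default. When both groups have zero
within-group variance the *t* statistic is undefined; the package adopts
*p* = 1 for equal means and *p* = 0 otherwise. FDR adjustment is
Benjamini–Hochberg step-up (statsmodels), applied across the common set only.

"Average RPKM" is the unweighted mean of the two group means. For the
balanced designs generated here this equals the grand mean over all samples;
for unbalanced data it weights groups equally, which is the more robust
reading.

The four criteria are conjunctive, so tightening any one of them can only
shrink the DET set — a property the test suite asserts directly. The
fold-change criterion is interpreted on the magnitude of the signed fold
change, covering down-regulation symmetrically.

## Signed fold change

fc = mean_LOCK / mean_RUN when mean_LOCK ≥ mean_RUN, else −(mean_RUN /
mean_LOCK); equal means give +1.0 by convention. Printed fold changes are
rounded half-up to three decimals; stored values stay unrounded, and the
results reader recovers the unrounded value from the stored full-precision
group means so that write→read is the identity.

## Annotation intersection

The chain operationalizes "associated with a condition" as membership in a
user-supplied transcript→condition table and "expression occurrences
matching the pathway" as per-condition direction concordance: a candidate
survives only if its observed direction (up/down in LOCK) equals the
expected direction for every listed condition, with `any` always matching
and a missing link treated as `any` (logged). This concordance rule is a
declared design choice — proprietary knowledge-base semantics cannot be
reproduced — and the chain's guarantees (each stage a subset of the
previous; invariance to annotation row order) hold for any annotation.

## Morphometry

Cell volume assumes a sphere: V(d) = (π/6)d³ µm³, with 10³ µm³ = 1 pl.
Mean cell mass is the mean of per-cell masses V(dᵢ)·ρ·10⁻⁹ g at lipid
density ρ = 0.915 ng/pl — not the mass of a cell at the mean diameter.
Because d³ is convex, the per-cell average is strictly larger for any
non-degenerate population (Jensen), and it is the only averaging consistent
with cellularity estimates derived from measured size distributions.
Cellularity = depot mass / mean cell mass. Size distributions use
left-closed, right-open 10-µm bins anchored at 0; per-bin group comparisons
run a *t*-test on per-animal bin percentages, with a bin that is empty in
every animal reported as missing rather than given a fabricated *p*.

## 2^ΔΔCt quantification

The inverted delta-Ct convention ΔCT = reference Ct − gene Ct is used, under
which larger ΔCT means higher expression. Relative expression per sample is
2^(ΔCT − mean ΔCT of RUN) for each gene, making the geometric mean of RUN
folds exactly 1. Group fold changes apply the signed convention to
group-mean relative expression. Statistical testing is performed on ΔCT
(log-scale, approximately normal under multiplicative noise) rather than on
the exponentiated folds. Duplicate wells are collapsed to their mean Ct on
table construction. The whole readout is invariant to a global shift of all
Ct values, asserted as a property test. Amplification-efficiency correction
is out of scope.

## Synthetic-data generator

The generator is the package's test bed and defines the conditions every
stochastic claim is measured under.

**Expression.** Each transcript gets a log-normal baseline abundance
(natural-log mean 1.5, sd 1.2 ⇒ median ≈ 4.5 RPKM, heavy right tail like
real RPKM distributions). Truth labels partition transcripts into null /
up / down / RUN-only / LOCK-only / unknown. Up-regulated transcripts have
LOCK mean = effect_fold × RUN mean before noise; down-regulated transcripts
are the mirror image with the baseline assigned to the high side in both
directions, so planted effects of either direction share the same
average-abundance distribution and the sensitivity metric treats them
symmetrically. Noise is multiplicative log-normal with mean 1 and
coefficient of variation `noise_cv` (default 0.2) — RPKM are ratio-scale
and heteroskedastic, so additive Gaussian noise would be unrealistic.
Values below the dropout floor (0.05 RPKM) are zeroed, giving the presence
filter genuine work; exclusive transcripts are forced exactly zero in the
silent group. Defaults emulate the modelled study's composition: 18,000
transcripts, 6% unannotated, 3.1% up / 0.74% down / 0.2% RUN-only / 1.4%
LOCK-only among all transcripts, n = 6 per group. The noise CV is a free
simulation parameter, not calibrated to data — the study reports no
dispersion estimates.

What the generator does *not* emulate: count-level sampling noise
(negative-binomial mean–variance coupling), library-size or length biases,
correlated transcripts, batch effects. Passing recovery tests therefore
demonstrates the cascade's correctness and calibration under a clean
multiplicative-noise model, not its power on any particular real dataset.

**Adipocytes.** Diameters are drawn from a normal truncated at zero
(negatives resampled; negligible at realistic coefficients of variation),
with ≥ 300 cells per animal as in standard practice.

**Ct tables.** Gene Ct = reference Ct − base offset − group effect (log2,
LOCK only) − Gaussian noise (sd default 0.05 cycles); the reference gene is
perfectly stable. This makes the planted log2 effect exactly the expected
ΔΔCt.

**Annotation.** `generate_condition_annotation` plants a chosen
any ⊇ all ⊇ concordant cardinality pattern over called DETs, making
intersection-chain behaviour fixture-reproducible.

All generators are pure functions of their spec including the seed.

## Problem sizes and numerical choices

Simulation-based tests and examples run at 2,000 transcripts (800–4,000 for
specific scenarios) with the design's n = 6 per group — large enough for
stable sensitivity/FDP estimates at the planted 4-fold effect, small enough
to keep the full suite under a few seconds. Recovery claims checked by the
suite, at fixed seeds: sensitivity ≥ 0.9 and false-discovery proportion
≤ 0.15 with 4-fold effects at 20% CV; mean significant fraction ≤ 0.1 on
null data over 20 seeds; qPCR fold recovery within 10% of planted effects.

Tabular I/O is TSV (UTF-8, '.' decimal) throughout; floats are parsed with
round-trip precision. Transcript identifiers are case-sensitive and never
remapped. Printed fold changes round half-up via `decimal`, avoiding
binary-float banker's rounding artefacts.

## Known limitations

- The *t*-test on raw RPKM with n = 6 has limited power for skewed
  transcripts; the cascade's published-style criteria, not the test alone,
  control the practical error rate.
- The equal-variance assumption is kept deliberately (a Welch option exists
  for the group-characteristics report only).
- Annotation semantics are a stand-in; results of the intersection chain are
  only as meaningful as the supplied annotation.
- Cellularity inherits the sphere and uniform-density assumptions; it is an
  order-of-magnitude estimator, not a stereological measurement.
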
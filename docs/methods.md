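# Methods

## Problem

In meningioma, loss of the short arm of chromosome 1 (1p) — usually
following 22q loss — marks tumors at elevated risk of recurrence, and
concurrent 1p/22q loss is discussed as a molecular criterion for upgrading
histologically benign (CNS WHO grade 1) tumors.  Copy-number calls come
from DNA-methylation arrays via conumee-style segmentation, so "1p loss"
must be operationalized as a threshold on the *fraction of the arm* covered
by loss segments.  Proposed thresholds have ranged from 5% to 30% of the
arm.  This package implements the quantification and the threshold analysis:
arm-level loss fractions, extent classes, cohort bin distributions, a
cut-off sweep scored by Harrell's concordance index (c-index), Kaplan–Meier
/ log-rank stratification, and the grade-1 co-loss rule — together with a
synthetic-cohort generator so the whole pipeline is testable without
patient-level data, which are not publicly deposited for the relevant
cohorts.

## Arm-level quantification

Coordinates are 0-based half-open everywhere; SEG files (conventionally
1-based closed) are converted at the I/O boundary.  Arm boundaries are the
min/max band coordinates per (chromosome, arm letter) from a UCSC cytoband
file; centromeric bands belong to their named arm, so p-end equals q-start.
Acrocentric p-arms consisting only of satellite/stalk bands are retained
but flagged unusable and refused by the fraction computation (no 0/0).

For one sample and one arm,

    loss_fraction = (arm bases covered by loss-called segments) / arm length,

with uncovered territory counted as neutral.  A segment is loss-called when
its log2 copy-ratio is strictly below −0.15, gain-called strictly above
+0.15.  **These thresholds are the largest acknowledged gap**: methylation
CNV pipelines leave the call threshold to the analyst and the relevant
publications do not print one.  ±0.15 is a common array heuristic; the
values are configurable and recorded in output metadata.  Overlapping
segments of one sample are resolved per base by the most extreme log2 ratio
(ties toward loss), which is deterministic and order-independent.
Fractions are base-pair-weighted by default ("95% of the arm" reads as
genomic extent); probe weighting is available.

Loss percentages are rounded half-away-from-zero to integer percent before
any rule is applied, because the rules are stated in integer percent.
Extent classes: **complete** iff >95%, **segmental** iff >5% and ≤95%,
**none** otherwise.  The cut-off rule is strict: at cut-off *c* a sample is
called "loss" iff its integer percent exceeds *c* — at the advocated 5%
cut-off, losses of 6% or more count.  Bin distributions isolate 0% in its
own bin and use left-open right-closed integer bins above it (width 5:
1–5, 6–10, …, 96–100), matching how such distributions are reported.

## Survival machinery

Implemented from first principles because the analyses depend on exact tie
conventions; each is locked to an independent oracle in the tests
(per-base labeling for fractions, O(n²) pair enumeration for the c-index,
hand-computed product limits, lifelines cross-checks on tie-free data).

* **Kaplan–Meier**: textbook product limit; events precede censorings at
  tied times.  The median is the smallest event time with S ≤ 0.5 and is
  *undefined* (not infinite) when the curve plateaus above 0.5 — honest
  reporting under heavy censoring.
* **Log-rank**: two-group, hypergeometric expectation/variance per event
  time, chi-square(1) upper tail, no continuity correction.  Zero variance
  returns statistic 0, p = 1 with a warning.
* **Harrell c-index**: pairs with distinct times are comparable iff the
  earlier time is an event; tied-time pairs are omitted unless exactly one
  is censored (the event subject counts as failing first); score ties among
  comparable pairs contribute 0.5.  With a binary loss call, within-group
  pairs are score ties, so even a perfectly separating call on >1 subject
  per group yields c < 1 — the sweep compares cut-offs on a common scale,
  not against 1.0.

The cut-off sweep evaluates the dichotomized loss indicator (the simplest
reading of "splitting cases at different cut-offs"), per cohort and never
pooled, over the integer grid 0–30% by default (covering the debated
5-versus-30 range).  Cut-offs leaving a cohort with zero loss-called or
zero non-loss subjects are reported as undefined rather than 0.5.  No
multiple-testing correction is applied across the sweep; it is descriptive,
and this is a known limitation.  The grade-1 analysis applies the same
cut-off to both arms and pools "no loss" with "single loss" into one
comparison group (a four-group breakdown is available).

## Synthetic cohorts: the stated world

The generator reproduces the structure described for methylation-profiled
meningioma series; defaults were fixed once, from the published numbers,
before any test was run:

| parameter | default | rationale |
|---|---|---|
| extent mixture (0% / segmental / 96–100%) | 0.55 / 0.10 / 0.35 | strong bimodality: most cases at 0% or 96–100% |
| segmental extents | Uniform(0.06, 0.95), telomere-anchored | partial losses rise toward the 1p telomere |
| p_artifact | 0.035 | 0.55·0.035 ≈ 1.9% of all cases show a focal 1–5% measured loss, matching the reported 44/2257 = 1.95% |
| noise sd (log2, per segment mean) | 0.04 | keeps whole-arm miscalls negligible; the 1–5% failure mode is modeled explicitly by the artifact mechanism, not by Gaussian tails |
| loss log2 mean | −0.45 | attenuated single-copy loss typical of array CNV |
| baseline hazard | 0.045 /yr | exponential median 15.4 y for intact tumors |
| hr_loss (any true 1p loss >5%) | 4.0 | gives a ≈12-year median RFS difference, near the reported 11.8 y |
| hr_co_loss (extra, 1p∧22q) | 1.5 | co-loss carries additional risk |
| censoring | exponential, 0.04 /yr | ~50% censoring in the intact group |
| 22q loss probability | 0.9 given 1p loss, 0.35 otherwise | 22q loss precedes 1p loss; >50% of meningioma carry it |
| MC mixture anchors | 94% Ben-1/2/3 at 0% loss; 72% Int-A/B+Mal at complete loss; linear interpolation in extent | the two published anchor compositions |

Survival times are exponential by default (closed-form medians and an
analytic c-index make recovery tests sharp); a Weibull shape parameter is
available.  All randomness flows from one seed through named sub-streams,
so cohorts are byte-identical under the same config and marginals stay
stable when one component's parameters change.

The analytic c-index for a binary call over exponential strata with common
exponential censoring uses the exact race probability
λ_s/(λ_s+λ_t+2c) for "subject from stratum *s* fails first and the pair is
comparable"; it is verified against a 10⁵-pair Monte-Carlo enumeration.

### What a green test does not establish

The simulator draws segment means as truth plus Gaussian noise; it does not
model probe-level intensities, tumor purity, interstitial multi-segment
losses (except as an option), batch effects, or the human visual-inspection
step used clinically.  Parameter-recovery results therefore validate the
pipeline's arithmetic and its discrimination behavior under the stated
world, not the clinical performance of any cut-off.

## Numerical and edge-case decisions

* "Co-loss KM lies below the comparison KM" is checked at the co-loss
  curve's own event times: before its first event both step functions are
  at 1, and an earlier event in the (larger) comparison group would make
  strict global dominance unattainable by construction.
* Integer base-pair arithmetic with a single final division makes the
  fraction oracle comparison exact (no floating-point tolerance).
* SEG floats are serialized with Python's shortest-exact repr so the
  read∘write round trip is lossless.
* The genome build of the upstream segmentation is not asserted; it is a
  provenance label carried through outputs.

## Known limitations

Cox covariate adjustment (age, grade), competing risks, interval censoring,
Uno's c-statistic, lift-over between builds and sex-chromosome ploidy are
out of scope.  The ±0.15 call threshold and the base-vs-probe weighting
choice are configurable precisely because the upstream convention is not
published.
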
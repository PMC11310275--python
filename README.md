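# armloss

Arm-level copy-number **loss quantification and prognostic cut-off analysis**
for meningioma recurrence risk.

Meningioma with loss of chromosome arm 1p — especially together with 22q
loss — recur earlier.  Copy-number calls from DNA-methylation arrays
(conumee-style segmentation) make "1p loss" a quantitative statement: the
fraction of the arm covered by loss segments.  This package implements the
analysis that turns that fraction into a clinically usable rule:

* per-sample, per-arm **loss/gain fractions** from SEG-format segments and
  a cytoband-derived arm coordinate system;
* extent classes (**none** ≤5%, **segmental** >5–95%, **complete** >95%)
  and the strict cut-off rule (at a 5% cut-off, losses of **6% or more**
  count);
* cohort **bin distributions** (0% isolated; 1–5, 6–10, …, 96–100) with
  optional methylation-class composition;
* a **cut-off sweep** scored per cohort by Harrell's c-index, first-
  principles **Kaplan–Meier** and **log-rank** machinery, and the
  **grade-1 concurrent 1p/22q co-loss** comparison;
* a **synthetic-cohort simulator** (bimodal loss extents, telomere-anchored
  partial losses, focal 1–5% artifacts, shifting methylation-class
  composition, proportional-hazards recurrence times) so every stage is
  testable without patient data.

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
from armloss import (
    SimulationConfig, simulate_cohort, profiles_for_arm,
    bin_distribution, sweep_cutoffs, stratify_by_cutoff,
)

cohort = simulate_cohort(SimulationConfig(n_subjects=500, n_cohorts=3, seed=1))
arm1p = cohort.arm_table.get("chr1", "p")
profiles = profiles_for_arm(cohort.segments, arm1p)

dist = bin_distribution(profiles, bin_width=5)
print(dist.to_frame().head(3).to_string(index=False))

sweep = sweep_cutoffs(profiles, cohort.clinical, cutoffs=range(0, 31))
print(f"mean c-index at 0%: {sweep.mean_c_index(0):.3f}, at 5%: {sweep.mean_c_index(5):.3f}")

strat = stratify_by_cutoff(profiles, cohort.clinical, cutoff_percent=0)
print(f"log-rank p = {strat.logrank.p_value:.3g}, "
      f"median RFS difference = {strat.median_difference:.2f} years")
```

prints

```
 bin  count
   0    788
 1-5     31
6-10      8
mean c-index at 0%: 0.681, at 5%: 0.691
log-rank p = 2.95e-115, median RFS difference = 11.87 years
```

Of 1500 simulated tumors, 788 have no 1p loss and 31 (2.1%) carry only a
focal 1–5% artifact loss; the c-index of the dichotomized loss call is
essentially flat across low cut-offs, and splitting survival at the 0%
cut-off separates median recurrence-free time by about 12 years.

The same pipeline runs from the shell:

```sh
armloss simulate --seed 1 -o sim/
armloss fractions --seg sim/segments.seg --cytoband sim/cytoband.txt --arm chr1p -o p1.tsv
armloss sweep --profiles p1.tsv --clinical sim/clinical.tsv --cutoffs 0:30 -o sweep.json
armloss km --profiles p1.tsv --clinical sim/clinical.tsv --cutoff 5 -o km
armloss grade1 --profiles-1p p1.tsv --profiles-22q p22.tsv --clinical sim/clinical.tsv -o g1.json
```

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch on a freshly
simulated three-cohort study (500 subjects per cohort): arm-fraction
quantification, 5%-bin distribution, the 0–30% cut-off sweep, Kaplan–Meier
stratification at the 0% and 5% cut-offs, the grade-1 co-loss comparison,
and the truth-recovery report, printing each stage's results.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
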
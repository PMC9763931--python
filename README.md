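# vhi — Vascular Health Index

`vhi` computes a composite, age-normalized score of microvascular health for
pressure-myography studies in the Zucker rat model of metabolic disease, and
provides the statistical machinery to validate it.  It is aimed at vascular
physiologists who want to pool heterogeneous isolated-vessel datasets —
across ages, cohorts and labs — onto a single "% of ideal vascular health"
scale.

## The index

Three aspects of microvascular health are measured per animal and vascular
bed (peripheral skeletal-muscle arterioles vs. cerebral arteries):

* **Reactivity** — dilator responses across agonist concentrations are fit
  with the logistic

  $$y = \min + \frac{\max - \min}{1 + 10^{\,\log EC_{50} - x}}$$

  where *x* is log₁₀ agonist concentration and *y* the diameter change
  (μm); the fitted upper bound *max* is the component value
  (acetylcholine, sodium nitroprusside).  The dilation to a single hypoxic
  challenge enters directly.

* **Wall mechanics** — from passive (Ca²⁺-free) pressure–diameter data,
  wall thickness WT = (OD − ID)/2, circumferential stress
  σ = P·ID/(2·WT) (1 mmHg = 1.334×10² N/m²) and strain
  ε = (ID − ID₅)/ID₅ (ID₅ at the 5 mmHg anchor) are computed at each
  pressure, and σ = σ₅·e^{βε} is fit by OLS on the log scale.  The
  stiffness coefficient β is the component; fits with r² ≤ 0.85 are
  rejected.

* **Network structure** — microvessel density (MVD, vessels/mm²) enters as
  a count.

Each component is scored as a percentage of the **standard of health** —
the mean in age-, bed- and study-matched untreated lean (LZR) controls:
ratio ×100 for quantities that fall with disease, and 200 − ratio ×100 for
β, which rises with disease (the excess over the standard counts as a
deficit; scores are deliberately **not clamped** and may go negative).  The
VHI is the unweighted mean of the component scores — 3-component
(ACh dilation, MVD, β) or 5-component (plus SNP and hypoxic dilation) — so
lean controls score 100 by construction.

Criterion validity (Pearson correlation of VHI with plasma insulin and
TNF-α, expected negative in obese animals) and discriminant validity
(Welch-test separation of lean, obese and treated-obese groups by VHI
alone) are built in, as is a synthetic cohort generator that manufactures
raw measurement series with known ground truth.

## Worked example

Group-mean-mode VHI for untreated obese (OZR) cerebral vessels at each age,
computed from the packaged published group summaries:

```python
from vhi import Bed, Group, Variant, load_reference

ref = load_reference()
for age in (7, 10, 13, 17, 20):
    res = ref.vhi(Bed.CEREBRAL, Group.OZR, age, Variant.FIVE_COMPONENT)
    print(age, round(res.score_pct, 2))
print("aggregate", round(ref.aggregate_vhi(Bed.CEREBRAL, Group.OZR,
                                           Variant.FIVE_COMPONENT), 2))
```

prints

```
7 91.44
10 87.84
13 77.08
17 65.56
20 52.8
aggregate 74.94
```

— a progressive decline from near-healthy at 7 weeks to roughly half the
lean standard at 20 weeks as metabolic disease develops.  At 17 weeks the
obese stiffness β is exactly twice the lean standard, so its component
score is 0; at 20 weeks the ratio is 245 % and the score is −45.5,
which the index averages in unchanged.

The same analysis end-to-end from raw synthetic measurements:

```bash
vhi simulate --out-dir data/ --seed 1 --bed cerebral
vhi compute --animals data/animals.csv --measurements-dir data/ \
    --bed cerebral --variant 5 --out scores.csv --summary-out summary.csv
vhi validate --scores scores.csv --animals data/animals.csv --biomarker insulin
```

`summary.csv` shows lean group means of exactly 100 at every age (the
definitional identity) and obese means tracking the published decline;
`validity.csv` shows the obese insulin–VHI correlation strongly negative
(r ≈ −0.9, p ≪ 0.001) and near zero in lean controls.

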
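# Methods

## The model

The Vascular Health Index (VHI) summarizes microvascular status as a
percentage of an "ideal" defined by healthy controls.  For animal *i* with
component measurements $m_{ic}$ and age/bed/study-matched lean-control
standards $s_c$ (the mean over matched untreated LZR controls),

$$\mathrm{VHI}_i = \frac{1}{|C|}\sum_{c\in C} \mathrm{score}_c(m_{ic}),
\qquad
\mathrm{score}_c(m) = \begin{cases}
100\, m/s_c & c \text{ falls with disease}\\
200 - 100\, m/s_c & c \text{ rises with disease (stiffness } \beta)
\end{cases}$$

with $C$ either the 3-component set {ACh dilation, MVD, β} or the
5-component set adding SNP and hypoxic dilation.  Key properties, all
enforced by tests:

* **No weighting.** There is no accepted rank ordering of reactivity, wall
  mechanics and network density, and the index predicts no outcome, so a
  regression-calibrated weighting would be unjustified; all components
  count equally.
* **No clamping.** The inverted β score must be allowed below zero: at the
  published 20-week cerebral values the β ratio is 245 %, and only an
  unclamped score of −45.5 makes the published 3-component value (33.2)
  reachable; clamping at zero would give ≈ 50.
* **Definitional identity.** Scoring lean controls against standards
  computed from themselves gives a per-component group mean of exactly 100
  (mean of $x_i/\bar x$ is 1), hence a group-mean VHI of exactly 100.

### Component extraction

* **Dilation upper bounds.** The logistic
  $y = \min + (\max-\min)/(1+10^{\log EC_{50}-x})$ is fit by trust-region
  nonlinear least squares with analytic starts (min ← smallest response,
  max ← largest, logEC50 ← concentration nearest the half-range crossing)
  and up to 5 deterministic jittered restarts.  logEC50 is bounded to the
  observed concentration range ± 2 log units so near-flat series cannot
  send it to infinity; an exactly flat series is refused as degenerate.
  Noiseless model data are recovered well below 0.1 % relative error.
* **Stiffness β.** Stress and strain are computed per pressure step (wall
  thickness recomputed at each step — the formulas are per-observation),
  and $\ln\sigma = \ln\sigma_5 + \beta\varepsilon$ is fit by OLS, which is
  the natural reading of an "ordinary least squares" fit of an exponential;
  r² is reported on that log scale and fits with r² ≤ 0.85 (strict) are
  rejected, contributing no component.  Rejected vessels are excluded and
  logged; no refit is attempted.  Negative strains are retained — no
  exclusion rule exists for them.
* **Hypoxic dilation** is a single scalar per animal (one PO₂ step, not a
  series) and passes through; negative values pass with a warning.
* **MVD** enters as a number; image analysis is out of scope.

### Scoring modes

Per-animal mode (score each animal, then average) is primary.  Group-mean
mode scores published group means directly against published lean means;
it replaces the mean of ratios by a ratio of means and therefore
approximates the per-animal group mean to roughly one percentage point at
the published dispersions.  It exists because the original per-animal
records are unpublished — only mean ± SE tables are available — and it is
what `scripts/acceptance.py` uses.  Standards are per-study lean means;
when study identifiers are absent a pooled-lean fallback is available
(logged).

## Validity analyses

* **Criterion validity**: Pearson r (two-sided p via the t transform,
  n − 2 df) between VHI and plasma insulin or TNF-α, per group, pooling
  animals across ages — the biomarkers and the vascular deficit both
  progress with age, and the published correlations pool the 7–20-week
  span.  Groups with < 3 complete pairs are skipped.
* **Discriminant validity**: at each (age, bed, variant), every non-lean
  group vs. lean, and every treated group vs. untreated obese, by
  two-sided Welch t-test at α = 0.05.  The original analysis does not name
  its test; Welch is chosen for robustness to unequal variance and group
  size, and this is a known departure risk when comparing exact p-values.
  No multiple-testing correction by default (matching the original
  presentation); Holm is available.

## Synthetic cohort generator

The generator emulates the study design: group × age × bed cells with the
published group sizes, component means and SEs (packaged in
`src/vhi/data/reference_cohort.yaml`, which doubles as the group-mean-mode
input).  Choices:

* Per-animal SD is reconstructed from the printed SE as $se\sqrt n$;
  per-cell distributions are Gaussian (no distributional information is
  published), truncated at 0 for positive quantities by redraw.
* A standard-normal latent severity per animal couples insulin and TNF-α
  (up) to component deviations (dilations/MVD down, β up) with per-group
  coefficient ρ (default 0.6 in diseased/treated groups, 0 in lean
  controls).  The within-animal covariance of components is unreported, so
  ρ is an assumption, user-settable in the spec; the residual component SD
  is scaled by $\sqrt{1-\rho^2}$ so the total per-animal SD stays
  $se\sqrt n$.
* Raw series are manufactured to fit back to the drawn values.
  Dose–response: 7 logistic points on log₁₀ concentration ∈ [−9, −6] with
  the drawn dilation as max, min ~ U(5, 15) μm, logEC50 ~ U(−7.8, −7.2),
  plus Gaussian measurement noise (default 1 μm).  Pressure series: at
  each protocol pressure (5, 20, …, 160 mmHg) the inner diameter solves
  σ(P, ID, WT) = σ₅·e^{βε(ID)} by bracketed root finding, with the wall
  linked to the lumen by a conserved wall annulus (incompressible wall,
  OD² − ID² fixed at the anchor) — a standard and physically motivated
  closure; any monotone WT(ID) law would serve.  The anchor wall thickness
  is set so the 5 mmHg stress equals σ₅ (default 2×10³ N/m², anchor ID
  drawn from U(90, 110) μm, giving ≈ 17 μm walls).  Noiseless series
  round-trip β to ≲ 10⁻⁶ relative.
* Determinism: one numpy Generator seeded from the spec (or an explicit
  seed) drives every draw in a fixed cell order, so identical spec + seed
  reproduce the cohort exactly.

What the generator does **not** emulate: within-animal correlation
structure beyond the single latent, non-Gaussian tails, inter-study
heterogeneity in standards (one synthetic study per bed), longitudinal
repeated measures, vasoconstrictor responses, and female animals (the
source cohorts are male-only).  Passing tests therefore demonstrate
correctness of the pipeline and calibration of the statistics under these
idealized conditions, not robustness to real-data pathologies such as
drop-out, batch effects or heteroscedastic measurement error.

## Numerical choices and degenerate inputs

* Ages are arbitrary positive integers — the construction lists 15 weeks
  among its age points although no 15-week data exist, so nothing is
  hard-coded to the observed {7, 10, 13, 17, 20}.
* One animal may contribute to both vascular beds under the same id; each
  bed is scored independently.
* Scores are carried at full double precision; rounding (1 decimal) is
  presentation only.
* Zero-variance inputs raise explicit errors (flat dose-response series,
  constant correlation variables); a Welch comparison of two identical
  constant groups reports p = 1.
* Missing biomarkers exclude an animal from criterion validity only;
  missing components exclude an animal from a variant only (it remains in
  the other variant if complete there).
* Orphan measurements (no matching animal record) are rejected at load
  time with counts and line numbers.

## Problem sizes

The test suite and acceptance script run at the published group sizes
(8–28 animals per cell).  Monte-Carlo checks use 200 replicates for fit
unbiasedness, criterion-validity and power properties, and 1000 replicates
for type-I calibration of the Welch test — sizes at which the binomial
uncertainty of the checked proportions is comfortably inside the asserted
margins.
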
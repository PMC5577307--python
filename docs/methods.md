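# Methods

This note documents the models, algorithms and defaults implemented in
`soaytel`, the choices made where the design was genuinely open, and what
the synthetic-data generator does and does not emulate.

## 1. Study structure emulated by the generator

One observation is a relative leukocyte telomere length (RTL) measurement
on a known animal: sample year (two August captures), age, sex, maternal and
paternal identity, maternal/paternal age at conception (MAC/PAC, integer
years ≥ 1) and qPCR plate.  The default design (`study_design()`) has 389
observations on 318 animals — 71 animals measured in both years — drawn from
pools of 208 mothers, 138 fathers and 9 plates, with the two-year split
200/189 and roughly 42% of observations on ~4-month-old lambs (age 0.33).

RTL is generated from the same crossed random-intercept Gaussian LMM the
analysis fits:

    rtl = μ + β_year·1[year₂] + β_age·age + β_sex·1[male] + β_as·age·1[male]
            + b_MAC·(MAC − E MAC) + b_PAC·(PAC − E PAC)
            + u_mother + u_father + u_plate + ε

Defaults: μ = 1 (RTL is calibrator-relative), all fixed-effect coefficients
zero (the parental-age tests are invariant to them), MAC/PAC slopes zero.

**Parental-age marginals.** Only the ranges and SD_PAC = 2.121 are pinned
down by the design, so MAC and PAC follow truncated geometric distributions
on [1, 14] and [1, 10], with the geometric parameter solved numerically so
the truncated SD hits its target (PAC 2.121; MAC defaults to 2.6 — wider,
as females reproduce to older ages).  MAC and PAC are drawn independently,
so their expected correlation is zero; repeated observations of an animal
share MAC, PAC and parents.

**Variance partition.** The total RTL SD targets 0.185.  The three random
intercepts jointly take `random_frac` (default 1/3) of the total variance,
split mother : father : plate = 16 : 2 : 82 — the mother and father shares
of the random-effects component reported for this design, with the plate
taking the remainder of that component.  The residual absorbs the rest of
the total variance.  The printed summaries do not pin down the
random-vs-residual split; 1/3 was chosen a priori as a middling value for
qPCR phenotypes with strong plate effects, and `partition_sensitivity()`
reports how power moves as this fraction varies — at the key slope of 0.012
the rejection rate changes by only a few points across 0.1–0.6, because the
plate component is nearly orthogonal to PAC.

**Limitations of the generator.** Parental ages are per-animal and
independent across animals, so paternal half-sibs conceived in the same
year do not share PAC as they would in a real pedigree; parent identities
are assigned uniformly (realised unique-parent counts fall slightly below
the pool sizes); there is no cohort structure in MAC/PAC, no
age–year confounding, and no simulation of extraction failures beyond a
configurable corrupt-triplicate injector.  Passing tests therefore show the
estimators are correct under the assumed structure, not that real data meet
that structure.

## 2. Raw plate simulation

`simulate_plates` inverts the RTL formula: given each record's RTL, the
plate's true efficiencies (defaults E_TEL = 1.91, E_B2M = 1.88) and fixed
calibrator Cqs (TEL 15, B2M 24; B2M sample Cqs get N(0, 0.3²) true
DNA-input spread), it solves for the sample Cqs so that processing
reproduces the RTL exactly.  Each sample yields TEL and B2M triplicates;
each plate carries two calibrator samples in triplicate per amplicon and
NTC triplicates.  A well's curve is

    F(c) = a + b·c + min(F₀·E^c, plateau),   F₀ = threshold·E^(−Cq_well)

with per-well linear baseline (a, b uniform in configurable ranges, default
zero), plateau 2.0, 50 cycles, optional lognormal fluorescence noise, and
per-well Cq noise N(0, cq_noise_sd²) (default 0.05 cycles — triplicate Cq
CVs ~0.2%, well inside the 5% QC limit, matching a well-behaved assay).
NTC wells contain baseline only.  Choosing F₀ from the threshold makes the
noiseless pipeline a round-trip identity by construction.

## 3. qPCR processing

* **Baseline.** A straight line fitted to the first 6 cycles is subtracted.
  If the raw early-cycle signal never exceeds 2% of the quantification
  threshold, no baseline of consequence can be present and the correction
  is skipped — this keeps the noiseless round trip exact to 1e-6, since
  regressing a line on the early tail of a pure exponential and subtracting
  it would otherwise distort the growth phase at the ~1% level (the
  accuracy observed, and tested, when real baselines are present).
* **Window of linearity.** Candidate windows of 4–6 cycles around the
  threshold crossing, ending before the plateau onset (first cycle within
  5% of the curve maximum), all with positive corrected fluorescence.
  Windows whose span contains the threshold are preferred outright (a Cq
  read outside the window is flagged `threshold_outside_window`); R² of the
  log-fluorescence regression decides among them, ties going to longer and
  earlier windows.  E = exp(slope); Cq interpolates the threshold crossing
  log-linearly.  Wells never reaching the threshold are `non_amplifying` —
  the expected NTC outcome; an amplifying NTC is flagged.
* **Group thresholds.** Defaults are the protocol constants 0.222 (TEL) and
  0.193 (B2M).  `set_group_threshold` reconstructs them: over the first 6
  plates, each well's provisional Cq is read at its window midpoint, and a
  constant threshold inside the common window span is root-found so the
  group-average interpolated Cq matches the average provisional Cq.
* **QC.** Triplicate CV is the sample SD over the mean of the three Cqs
  (cycle scale); CV > 5% on either amplicon excludes the sample, as does
  any replicate whose efficiency deviates > 5% from the plate × amplicon
  mean.  A triplicate with a failed well is excluded, not averaged over two
  wells.  Cut-offs are strict where phrased as "higher than" (integrity
  > 2, CV > 5%, deviation > 5%) and inclusive at printed interval endpoints.
  Every exclusion carries one primary reason code and per-stage counts are
  reported in the run manifest.  Plate-mean efficiencies are computed over
  QC-eligible sample and calibrator wells before sample-level exclusions
  (NTCs never contribute); a config switch recomputes them after.
* **DNA QC.** Yield ≥ 20 ng/µl, 260/280 in [1.7, 2.0], 260/230 in
  [1.8, 2.2], gel integrity ≤ 2; one re-extraction retry before final
  exclusion.

## 4. Mixed model and tests

The LMM has crossed random intercepts for mother, father and plate.
Animal identity is deliberately *not* a random term by default, matching
the analysis this package reproduces (an option exists via
`ModelSpec.random`).  Fitting maximises the likelihood profiled over the
variance ratios γ_k = σ_k²/σ_e² (β and σ_e² closed-form given γ) with an
analytic gradient; all linear algebra runs through the q×q random-effect
cross-product (Woodbury identity), so cost per evaluation is O(q³),
independent of n.  L-BFGS-B with box bounds γ ≥ 0 allows components to sit
exactly at the zero boundary (reported, never refitted without the term);
an "abnormal" line-search stop right at the optimum is accepted when the
projected gradient is < 1e-3, and a Nelder-Mead pass rescues genuine
failures, which are flagged on the result, never silent.  The fit is
deterministic given data and spec, invariant to row order and identifier
relabelling (tested).  Correctness is cross-checked against a generic
dense-covariance optimizer and against statsmodels' MixedLM
variance-component formulation.

LRTs compare ML fits: χ² = 2Δℓ clipped at 0, df = difference in
fixed-effect counts, upper-tail χ² p-value with no boundary correction
(the tested terms are fixed effects, so standard asymptotics apply; the
null distribution of the 1-df statistic is verified against χ²(1) by
simulation).  MAC/PAC are mean-centred before squaring — centring changes
nothing at the LRT level but conditions the quadratic fit.  Quadratic tests
are joint 2-df comparisons against the base model.  `lamb_mode` drops age
and age×sex for the same-age lamb subset.  `variance_proportions` reports
each intercept's share of the random-effects component (residual excluded;
`include_residual=True` switches to shares of total variance).

## 5. Power analysis

`estimate_power` redraws the complete design (parents, plates, covariates,
RTL) each replicate at an injected PAC slope and counts 1-df LRT rejections
at α = 0.05.  One master `SeedSequence` spawns independent substreams per
effect and replicate, so runs are reproducible and grid points independent.
Non-converged replicates are dropped from the denominator with a warning;
more than 2% dropped aborts the run (in practice none drop).
`minimum_detectable_effect` makes the estimated curve non-decreasing
(pool-adjacent-violators) and inverts it linearly between the bracketing
grid points, reporting the bracket and its Monte-Carlo SEs.  Effect sizes
convert to correlations by r = slope·SD_PAC/SD_RTL (SD_PAC = 2.121,
SD_RTL = 0.185), with `r_to_slope` the exact inverse.

Problem sizes: the test suite uses 500 replicates for the power check at
slope 0.012, 200 at the r = 0.378 equivalent, 1000 for the type-I
calibration, and 100 for the isotonic power-curve check; the
variance-share recovery uses a 10 000-observation design with 800/400/400
levels so each share is estimable to better than ±3 points.

## 6. Numerical notes and edge cases

* RTL must be positive; the generator redraws the rare residuals that
  would produce RTL ≤ 0 (probability < 1e-7 per observation at defaults).
* The truncated-geometric parameter is solved by bisection; the target SD
  must be below the discrete-uniform SD of the range.
* `compute_rtl` requires plate-mean efficiencies > 1 and a calibrator on
  the plate; a missing calibrator excludes the plate's samples with reason
  `no_calibrator`.
* Degenerate inputs: all-zero random variances make `variance_proportions`
  return a flagged empty result; models without random terms collapse to
  OLS; curves shorter than 30 cycles, non-monotone cycle vectors or
  non-finite fluorescence are rejected at construction.
* All tables are plain CSV with header rows (no community binary standard
  exists for qPCR well tables); configs are YAML with unknown keys
  rejected; manifests are JSON and include per-stage counts that reconcile
  (generated = analyzed + excluded) plus SHA-256 digests of the written
  tables.
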
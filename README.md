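# soaytel

Parental-age effects on offspring leukocyte telomere length in a wild sheep
population: the full quantitative pipeline, from raw qPCR amplification
curves to mixed-model likelihood-ratio tests and simulation-based power
analysis, exercisable end to end on synthetic data.

## Who this is for

Evolutionary ecologists and biostatisticians analysing relative telomere
length (RTL) measured by qPCR in a pedigreed wild population, asking whether
maternal or paternal age at conception (MAC/PAC) predicts offspring RTL —
and, when the answer is "no evidence", quantifying how large an effect the
study could actually have detected.

## The science in brief

**Measurement.** Telomeric (TEL) and single-copy reference (B2M) amplicons
are run in triplicate on each plate alongside a calibrator sample.  After
linear baseline correction, each well's reaction efficiency E and
quantification cycle Cq are estimated from the window of linearity of its
log fluorescence.  Relative telomere length is the calibrator- and
efficiency-corrected ratio

```
RTL = E_TEL^(CqTEL[cal] − CqTEL[sample]) / E_B2M^(CqB2M[cal] − CqB2M[sample])
```

with plate-mean efficiencies and triplicate-mean Cqs.  QC excludes samples
with triplicate Cq CV > 5%, wells whose efficiency deviates > 5% from the
plate × amplicon mean, and DNA extractions failing yield (≥ 20 ng/µl),
absorbance (260/280 in 1.7–2.0, 260/230 in 1.8–2.2) or gel-integrity
(score ≤ 2) checks, with one re-extraction retry.

**Model.** RTL is modelled with a Gaussian linear mixed model with crossed
random intercepts,

```
RTL = β₀ + β₁·year + β₂·age + β₃·sex + β₄·age×sex (+ b·PAC [+ c·PAC²])
      + u_mother + u_father + u_plate + ε ,
```

and MAC/PAC terms are tested with 1-df (linear) or 2-df (joint quadratic)
likelihood-ratio tests between ML fits.

**Power.** Because a null result is only informative alongside power, the
package estimates Monte-Carlo power: simulate the full design afresh at a
candidate true slope, run the PAC test, and count rejections at α = 0.05.
Slopes convert to cross-study comparable correlations via
`r = slope · SD_PAC / SD_RTL`.

## Worked example

```python
from soaytel import sample_population, study_design, test_parental_age

phen = sample_population(study_design(), seed=6)   # 389 obs, 318 animals
res = test_parental_age(phen, which="pac", order="linear")
print(f"chisq({res.df}) = {res.chisq:.3f}, p = {res.p_value:.3f}")
```

prints (null simulation — no PAC effect was injected):

```
chisq(1) = 1.871, p = 0.171
```

i.e. the linear PAC term does not improve on the base model.  The
`examples/` scripts walk through each capability; `examples/04_power_analysis.py`
prints, among other lines:

```
slope 0.012 -> r = 0.138 (human-scale effect)
r 0.378 -> slope = 0.0330 (chimpanzee-scale effect)
```

A thin CLI wraps the same functions:

```sh
soaytel simulate --seed 1           # phenotypes.csv + plates.csv
soaytel process-qpcr plates.csv     # rtl.csv with QC report
soaytel fit phenotypes.csv --term pac
soaytel power --effects 0,0.006,0.012 --reps 200
soaytel run-all --outdir runs/demo  # full pipeline + manifest.json
```

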
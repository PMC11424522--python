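# growthref

Age- and sex-specific anthropometric growth references for adolescents,
built with the LMS (Box–Cox Cole–Green) method.

Growth monitoring compares a child's height, weight or BMI against a
reference distribution for their age and sex. `growthref` is for
biostatisticians and public-health researchers who need to *construct*
such a reference from a cross-sectional survey — here, a cohort of
adolescents aged 12–16 — rather than borrow WHO/CDC charts that may not
fit a local population. The package fits the reference, renders
percentile tables and charts, cross-validates it, and compares its
medians with international standards. Because survey microdata are
rarely shareable, a first-class synthetic-cohort generator reproduces
the statistical structure the method assumes, so the whole pipeline is
testable offline.

## The model

Within one age–sex cell, a positive measurement *Y* follows a
Box–Cox-normal distribution summarized by three parameters: the Box–Cox
power **L** (skewness), the median **M**, and the coefficient of
variation **S**. The transformed value

```
Z = ((Y/M)^L − 1) / (L·S)        (L ≠ 0)
Z = ln(Y/M) / S                  (L = 0)
```

is standard normal, so the 100·p-th percentile is

```
C_p = M · (1 + L·S·z_p)^(1/L)    (L ≠ 0),     C_p = M · e^(S·z_p)    (L = 0)
```

with `z_p = Φ⁻¹(p)` at full floating precision. L, M, S are estimated
per cell by maximizing the implied log-likelihood

```
ℓ = Σ [ (L−1)·ln y − L·ln M − ln S − ½·ln 2π − z²/2 ]
```

The reference is validated by **back-substitution**: refit on a random
half of each cell and compare the refitted medians with the full-data
medians; the mean absolute percentage error (MAPE) is classified with
the Lewis bands (<10% "Highly accurate", 10–20% "Good", 20–50%
"Reasonable", >50% "Inaccurate").

## Worked example

```python
from growthref import LMSTriple, centile, zscore, PercentileSpec

params = LMSTriple(lam=3.020, mu=149.72, sigma=0.069)  # boys' height, age 12
print(f"P90 = {centile(params, PercentileSpec.from_p(0.90)):.2f} cm")
print(f"z(140 cm) = {zscore(140.0, params):+.2f}")
```

prints

```
P90 = 161.93 cm
z(140 cm) = -0.88
```

— the 90th height percentile for 12-year-old boys under this reference
is 161.93 cm, and a boy measuring 140 cm stands 0.88 standard deviations
below the reference median.

The full pipeline runs from one config, in Python

```python
from growthref import RunConfig
from growthref.pipeline import run_pipeline

result = run_pipeline(RunConfig(seed=20190401, outdir="run"))
print(result["validation"].summaries)
```

or from the shell: `growthref run --outdir run`. With the default
conditions (2,970 simulated adolescents, 297 per age–sex cell) the
back-substitution summary looks like

```
      sex measure  mean_signed_error  mape_percent   accuracy_class
0  female     bmi           0.000569      0.431799  Highly accurate
1  female  height          -0.001831      0.317342  Highly accurate
2  female  weight          -0.002333      0.718679  Highly accurate
3    male     bmi          -0.001114      0.349071  Highly accurate
4    male  height           0.001980      0.236544  Highly accurate
5    male  weight          -0.005843      1.355890  Highly accurate
```

— every measure lands in the "Highly accurate" band, i.e. the reference
is stable under subsampling. The `examples/` directory holds one short
script per capability (centiles/z-scores, simulate-and-fit,
back-substitution, international comparison, charts).

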
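"""Evaluate centiles and z-scores from a published LMS row.

The LMS triple below is the boys' height reference at age 12
(L = Box-Cox power, M = median in cm, S = coefficient of variation).
Any percentile follows in closed form, and a child's measurement maps
back to a z-score within the age-sex reference distribution.
"""

from growthref import LMSTriple, PercentileSpec, centile, zscore

params = LMSTriple(lam=3.020, mu=149.72, sigma=0.069)

print("boys' height at age 12 (L=3.020, S=0.069, M=149.72):")
for pct in (3, 10, 35, 50, 65, 90):
    spec = PercentileSpec.from_p(pct / 100)
    print(f"  {spec.label:>4}: {centile(params, spec):7.2f} cm")

# a 12-year-old boy measuring 140 cm relative to this reference
print(f"\nz-score of 140 cm: {zscore(140.0, params):+.2f}")
print("(negative: below the reference median; -1.88 would be about P3)")
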
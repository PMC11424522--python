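"""Compare the published local medians with international standards.

Differences are local P50 minus external P50 per overlapping
(sex, age, measure) key; negative values mean the local population sits
below the external standard.
"""

from growthref import compare_medians
from growthref.datasets import load_international_medians, load_published_reference

local = load_published_reference()
comparison = compare_medians(local, load_international_medians())

boys_weight = comparison.summaries.query("sex == 'male' and measure == 'weight'")
print("boys' weight P50 differences vs external sources (kg):")
for _, row in boys_weight.iterrows():
    print(
        f"  vs {row['source']:>7}: min {row['min_difference']:+6.2f}, "
        f"max {row['max_difference']:+6.2f}, mean {row['mean_difference']:+6.2f}"
    )
print("\nall negative: local boys weigh less than every reporting standard.")
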
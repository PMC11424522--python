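"""Render smoothed percentile growth charts from the published reference.

One curve per percentile, age on the horizontal axis; the curves never
cross because the LMS centile transform is monotone in p at every age.
"""

from pathlib import Path

from growthref.charts import render_chart
from growthref.datasets import load_published_reference

table = load_published_reference()
outdir = Path("charts")
outdir.mkdir(exist_ok=True)
for sex in ("male", "female"):
    for measure in ("height", "weight", "bmi"):
        path = outdir / f"{sex}_{measure}.png"
        render_chart(table, measure, sex, path)
        print(f"wrote {path}")
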
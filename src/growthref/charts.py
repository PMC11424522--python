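"""Percentile-chart rendering: one smoothed curve per percentile, age on
the horizontal axis."""

from __future__ import annotations

from matplotlib.backends.backend_agg import FigureCanvasAgg  # noqa: F401  (Agg forces headless rendering)
from matplotlib.figure import Figure

from .errors import ValidationError
from .reference import PercentileTable

__all__ = ["chart_series", "render_chart"]

_YLABELS = {"height": "height (cm)", "weight": "weight (kg)", "bmi": "BMI (kg/m$^2$)"}


def chart_series(
    table: PercentileTable, measure: str, sex: str
) -> tuple[list[int], dict[str, list[float]]]:
    """The exact (age, value) series a chart plots, one per percentile label.

    Exposed separately so the no-crossing property of the plotted curves
    can be checked on the data rather than on pixels.
    """
    if measure not in table.percentile_sets:
        raise ValidationError(f"unknown measure {measure!r}")
    rows = [r for r in table.rows if r.measure == measure and r.sex == sex]
    if not rows:
        raise ValidationError(f"no rows for sex={sex!r}, measure={measure!r}")
    ages = sorted(r.age_group for r in rows)
    if len(ages) < 2:
        raise ValidationError("charting needs at least two ages")
    by_age = {r.age_group: r for r in rows}
    specs = sorted(table.percentile_sets[measure], key=lambda s: s.p)
    series = {
        spec.label: [by_age[a].percentiles[spec.label] for a in ages] for spec in specs
    }
    return ages, series


def render_chart(
    table: PercentileTable, measure: str, sex: str, path, dpi: int = 150
) -> None:
    """Render the percentile curves for one sex and measure to ``path``.

    Output format follows the file extension (PNG or SVG); rendering is
    deterministic for fixed inputs.
    """
    ages, series = chart_series(table, measure, sex)
    fig = Figure(figsize=(6.0, 4.5))
    ax = fig.subplots()
    for label, values in series.items():
        ax.plot(ages, values, marker="o", markersize=3, label=label)
        ax.annotate(
            label,
            (ages[-1], values[-1]),
            textcoords="offset points",
            xytext=(6, -3),
            fontsize=8,
        )
    ax.set_xlabel("age (completed years)")
    ax.set_ylabel(_YLABELS.get(measure, measure))
    ax.set_title(f"{sex} {measure} percentile curves")
    ax.set_xticks(ages)
    ax.legend(fontsize=8, loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
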
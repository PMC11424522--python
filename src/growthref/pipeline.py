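"""End-to-end orchestration: simulate -> fit -> validate -> compare -> chart.

Everything is driven by one :class:`~growthref.config.RunConfig`; all
artifacts land in the configured output directory and every stage result
is also returned in memory.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import __version__
from .charts import render_chart
from .compare import compare_medians
from .config import RunConfig
from .datasets import load_international_medians
from .io import (
    write_cohort,
    write_comparison,
    write_percentile_table,
    write_validation_report,
)
from .reference import MEASURES, build_reference
from .simulate import generate_cohort
from .validation import back_substitution

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Run the full pipeline from one configuration, offline.

    Returns a dict with the in-memory ``cohort``, ``reference``,
    ``validation`` and ``comparison`` objects plus the paths written.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"package_version": __version__, "seed": config.seed}

    log.info("simulating cohort (%d per cell)", config.n_per_cell)
    cohort = generate_cohort(config.cohort_spec())
    cohort_path = out / "cohort.csv"
    write_cohort(cohort, cohort_path, provenance)

    log.info("fitting reference grid")
    options = config.build_options()
    reference = build_reference(cohort, options)
    reference_path = out / "reference.csv"
    write_percentile_table(reference, reference_path, provenance)

    log.info("back-substitution validation (fraction=%s)", config.validation_fraction)
    report = back_substitution(
        cohort,
        fraction=config.validation_fraction,
        seed=config.seed,
        options=options,
        reference=reference,
    )
    validation_path = out / "validation.csv"
    write_validation_report(report, validation_path, provenance)

    log.info("comparing against packaged international medians")
    comparison = compare_medians(reference, load_international_medians())
    comparison_path = out / "comparison.csv"
    write_comparison(comparison, comparison_path, provenance)

    chart_paths = []
    for sex in config.sexes:
        for measure in MEASURES:
            path = out / f"chart_{sex}_{measure}.{config.chart_format}"
            render_chart(reference, measure, sex, path, dpi=config.chart_dpi)
            chart_paths.append(path)

    return {
        "cohort": cohort,
        "reference": reference,
        "validation": report,
        "comparison": comparison,
        "paths": {
            "cohort": cohort_path,
            "reference": reference_path,
            "validation": validation_path,
            "comparison": comparison_path,
            "charts": chart_paths,
        },
    }
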
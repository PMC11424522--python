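"""Back-substitution cross-validation of a fitted reference.

The procedure refits the LMS model on a seeded random subsample within
each (sex, age, measure) cell and compares the refitted medians (fitted
P50) with the full-data reference medians (actual P50).  Per cell the
signed relative error ``(actual - fitted) / actual`` is reported; per
(sex, measure) both the mean of the unrounded signed errors and the true
mean absolute percentage error (MAPE, in percent) are reported, and the
MAPE is classified with the Lewis accuracy bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .lms import FitOptions, MeasurementSample, fit_group
from .reference import MEASURES, BuildOptions, PercentileTable, build_reference, stratify

__all__ = [
    "LEWIS_BANDS",
    "ValidationReport",
    "relative_error",
    "classify_mape",
    "back_substitution",
    "summarize_errors",
]

#: Lewis (1982) forecasting-accuracy bands on MAPE (%); intervals are
#: left-closed, so a MAPE of exactly 10 falls in the "Good" band.
LEWIS_BANDS: tuple[tuple[float, str], ...] = (
    (10.0, "Highly accurate"),
    (20.0, "Good"),
    (50.0, "Reasonable"),
    (float("inf"), "Inaccurate"),
)

ROW_COLUMNS = ["sex", "measure", "age", "actual_p50", "fitted_p50", "signed_rel_error"]
SUMMARY_COLUMNS = ["sex", "measure", "mean_signed_error", "mape_percent", "accuracy_class"]


def relative_error(actual: float, fitted: float) -> float:
    """Signed relative error ``(actual - fitted) / actual``, unrounded.

    The published per-row quantity is this value rounded to two decimals;
    rounding is left to the report layer.
    """
    if not actual > 0:
        raise DomainError(f"actual value must be positive, got {actual}")
    return (actual - fitted) / actual


def classify_mape(mape_percent: float) -> str:
    """Lewis accuracy class of a MAPE given in percent."""
    if mape_percent < 0:
        raise DomainError(f"MAPE cannot be negative, got {mape_percent}")
    for upper, label in LEWIS_BANDS:
        if mape_percent < upper:
            return label
    raise AssertionError("unreachable")


@dataclass
class ValidationReport:
    """Back-substitution output.

    ``rows`` holds per-cell actual/fitted P50 and signed relative errors;
    ``summaries`` holds per (sex, measure) the mean signed error of the
    unrounded rows, the true MAPE (%) and its Lewis class.
    """

    rows: pd.DataFrame
    summaries: pd.DataFrame
    fraction: float
    seed: int | None

    def __eq__(self, other) -> bool:  # round-trip identity
        if not isinstance(other, ValidationReport):
            return NotImplemented
        return (
            self.fraction == other.fraction
            and self.seed == other.seed
            and self.rows.reset_index(drop=True).equals(other.rows.reset_index(drop=True))
            and self.summaries.reset_index(drop=True).equals(
                other.summaries.reset_index(drop=True)
            )
        )


def summarize_errors(rows: pd.DataFrame) -> pd.DataFrame:
    """Per (sex, measure) mean signed error, true MAPE and Lewis class."""
    records = []
    for (sex, measure), sub in rows.groupby(["sex", "measure"], sort=True):
        errors = sub["signed_rel_error"].to_numpy(dtype=float)
        mape = float(np.mean(np.abs(errors)) * 100.0)
        records.append(
            {
                "sex": sex,
                "measure": measure,
                "mean_signed_error": float(np.mean(errors)),
                "mape_percent": mape,
                "accuracy_class": classify_mape(mape),
            }
        )
    return pd.DataFrame(records, columns=SUMMARY_COLUMNS)


def back_substitution(
    cohort: pd.DataFrame,
    fraction: float = 0.5,
    seed: int | None = None,
    options: BuildOptions | None = None,
    reference: PercentileTable | None = None,
) -> ValidationReport:
    """Refit on a seeded stratified subsample and compare medians.

    A simple random subsample without replacement of the given fraction is
    drawn within each (sex, age, measure) group, the LMS model is refitted
    per group, and its median is compared with the full-data reference
    median.  ``fraction=1`` reuses every record, so every error is exactly
    zero (the fitter is deterministic).  Fully reproducible given the seed.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must lie in (0, 1], got {fraction}")
    if seed is None:
        raise ValidationError("an explicit seed is required for reproducibility")
    opts = options or BuildOptions()
    if reference is None:
        reference = build_reference(cohort, opts)
    groups = stratify(cohort, opts.age_window)
    rng = np.random.default_rng(seed)

    too_small: list[tuple[str, int, str]] = []
    records = []
    lo, hi = opts.age_window
    # fixed iteration order so the RNG stream is reproducible
    for sex in opts.sexes:
        for measure in MEASURES:
            for age in range(lo, hi + 1):
                key = (sex, age, measure)
                values = groups.get(key)
                if values is None or values.size == 0:
                    continue
                k = int(round(fraction * values.size))
                if k < opts.fit.min_group_size:
                    too_small.append(key)
                    continue
                idx = rng.choice(values.size, size=k, replace=False)
                sub = values[idx]
                fitted = fit_group(MeasurementSample(sub, measure=measure), opts.fit)
                fitted_mu = fitted.mu
                actual_mu = reference.get_row(sex, age, measure).params.mu
                records.append(
                    {
                        "sex": sex,
                        "measure": measure,
                        "age": age,
                        "actual_p50": actual_mu,
                        "fitted_p50": fitted_mu,
                        "signed_rel_error": relative_error(actual_mu, fitted_mu),
                    }
                )
    if too_small:
        raise ValidationError(
            f"subsample below minimum fit size in groups: {sorted(too_small)}"
        )
    rows = pd.DataFrame(records, columns=ROW_COLUMNS)
    return ValidationReport(
        rows=rows,
        summaries=summarize_errors(rows),
        fraction=float(fraction),
        seed=int(seed),
    )
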
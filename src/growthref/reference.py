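"""Build age- and sex-specific percentile reference tables from a cohort.

A cohort is a :class:`pandas.DataFrame` with one row per subject
(``id, sex, age_years, age_group, height_cm, weight_kg, bmi``).  Records
are stratified by sex and completed year of age, each (sex, age, measure)
cell gets a maximum-likelihood LMS fit, the three parameter series can
optionally be smoothed across age, and the configured percentile set is
evaluated per cell to produce the published-table artifact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, GrowthRefError, ValidationError
from .lms import (
    BMI_PERCENTILES,
    HEIGHT_WEIGHT_PERCENTILES,
    FitOptions,
    LMSTriple,
    MeasurementSample,
    PercentileSpec,
    centile,
    fit_group,
)

__all__ = [
    "MEASURES",
    "SEXES",
    "AnthropometricRecord",
    "ReferenceRow",
    "PercentileTable",
    "BuildOptions",
    "compute_bmi",
    "stratify",
    "build_reference",
    "smooth_series",
    "median_growth_summary",
    "default_percentile_sets",
]

log = logging.getLogger(__name__)

MEASURES: tuple[str, ...] = ("height", "weight", "bmi")
SEXES: tuple[str, ...] = ("male", "female")

#: cohort DataFrame column holding each measure
MEASURE_COLUMNS: dict[str, str] = {
    "height": "height_cm",
    "weight": "weight_kg",
    "bmi": "bmi",
}


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index: weight in kg over squared height in metres."""
    if not (weight_kg > 0):
        raise ValidationError(f"weight must be positive, got {weight_kg}")
    if not (height_cm > 0):
        raise ValidationError(f"height must be positive, got {height_cm}")
    height_m = height_cm / 100.0
    return weight_kg / (height_m * height_m)


@dataclass(frozen=True)
class AnthropometricRecord:
    """One subject's validated measurements; BMI is always recomputed."""

    subject_id: str
    sex: str
    age_years: float
    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex code {self.sex!r}")
        if not (self.age_years >= 0):
            raise ValidationError(f"age must be nonnegative, got {self.age_years}")
        if not (self.height_cm > 0):
            raise ValidationError("height must be positive")
        if not (self.weight_kg > 0):
            raise ValidationError("weight must be positive")

    @property
    def age_group(self) -> int:
        return int(math.floor(self.age_years))

    @property
    def bmi(self) -> float:
        return compute_bmi(self.weight_kg, self.height_cm)


def records_to_frame(records: Iterable[AnthropometricRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.subject_id,
            "sex": r.sex,
            "age_years": r.age_years,
            "age_group": r.age_group,
            "height_cm": r.height_cm,
            "weight_kg": r.weight_kg,
            "bmi": r.bmi,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "sex", "age_years", "age_group", "height_cm", "weight_kg", "bmi"],
    )


def default_percentile_sets() -> dict[str, tuple[PercentileSpec, ...]]:
    return {
        "height": HEIGHT_WEIGHT_PERCENTILES,
        "weight": HEIGHT_WEIGHT_PERCENTILES,
        "bmi": BMI_PERCENTILES,
    }


@dataclass(frozen=True)
class ReferenceRow:
    """One published-table row: fitted parameters plus evaluated percentiles."""

    sex: str
    age_group: int
    measure: str
    params: LMSTriple
    percentiles: dict[str, float]
    n: int | None = None

    def __post_init__(self) -> None:
        vals = list(self.percentiles.values())
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValidationError(
                f"{self.sex}/{self.age_group}/{self.measure}: percentile values "
                "must increase strictly with p"
            )


@dataclass
class PercentileTable:
    """A fitted reference: one row per (sex, age, measure) in the grid."""

    rows: list[ReferenceRow]
    percentile_sets: dict[str, tuple[PercentileSpec, ...]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(r.sex, r.age_group, r.measure) for r in self.rows]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (sex, age, measure) rows in table")

    def get_row(self, sex: str, age_group: int, measure: str) -> ReferenceRow:
        for row in self.rows:
            if (row.sex, row.age_group, row.measure) == (sex, age_group, measure):
                return row
        raise KeyError((sex, age_group, measure))

    def p50_series(self, sex: str, measure: str) -> dict[int, float]:
        """Median (P50) by age for one sex and measure; P50 equals mu."""
        return {
            row.age_group: row.params.mu
            for row in self.rows
            if row.sex == sex and row.measure == measure
        }

    def ages(self) -> list[int]:
        return sorted({row.age_group for row in self.rows})

    def to_frame(self) -> pd.DataFrame:
        labels: list[str] = []
        for specs in self.percentile_sets.values():
            for spec in specs:
                if spec.label not in labels:
                    labels.append(spec.label)
        labels.sort(key=lambda s: PercentileSpec.from_label(s).p)
        data = []
        for row in self.rows:
            rec = {
                "sex": row.sex,
                "age_group": row.age_group,
                "measure": row.measure,
                "n": row.n,
                "lam": row.params.lam,
                "mu": row.params.mu,
                "sigma": row.params.sigma,
            }
            for label in labels:
                rec[label] = row.percentiles.get(label)
            data.append(rec)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class BuildOptions:
    """Everything :func:`build_reference` needs beyond the cohort itself."""

    sexes: tuple[str, ...] = SEXES
    age_window: tuple[int, int] = (12, 16)
    percentile_sets: Mapping[str, tuple[PercentileSpec, ...]] | None = None
    fit: FitOptions = field(default_factory=FitOptions)
    smoothing_edf: int | None = None  # None = raw per-age fits (default)
    skip_unfittable: bool = False
    params_override: Mapping[tuple[str, int, str], LMSTriple] | None = None

    def resolved_percentile_sets(self) -> dict[str, tuple[PercentileSpec, ...]]:
        sets = default_percentile_sets()
        if self.percentile_sets:
            sets.update(self.percentile_sets)
        return sets


def stratify(
    cohort: pd.DataFrame, age_window: tuple[int, int] = (12, 16)
) -> dict[tuple[str, int, str], np.ndarray]:
    """Group measurement values by (sex, completed-year age, measure).

    Records outside the inclusive age window are excluded with a logged
    count; every in-window record contributes to exactly three measure
    groups.
    """
    lo, hi = age_window
    if "age_group" not in cohort.columns:
        cohort = cohort.assign(age_group=np.floor(cohort["age_years"]).astype(int))
    in_window = cohort[(cohort["age_group"] >= lo) & (cohort["age_group"] <= hi)]
    excluded = len(cohort) - len(in_window)
    if excluded:
        log.info("stratify: excluded %d records outside ages [%d, %d]", excluded, lo, hi)
    groups: dict[tuple[str, int, str], np.ndarray] = {}
    for (sex, age), sub in in_window.groupby(["sex", "age_group"], sort=True):
        for measure in MEASURES:
            values = sub[MEASURE_COLUMNS[measure]].to_numpy(dtype=float)
            groups[(str(sex), int(age), measure)] = values
            log.debug("group %s/%s/%s: n=%d", sex, age, measure, values.size)
    return groups


def smooth_series(
    series: Mapping[int, LMSTriple], edf: int
) -> dict[int, LMSTriple]:
    """Smooth the L, M and S sequences across age by least squares.

    Each parameter series is replaced by a degree ``edf - 1`` polynomial
    fit evaluated on the age grid.  ``edf`` equal to the number of ages is
    the interpolation limit and returns the series unchanged; a constant
    series is unchanged for every ``edf``.
    """
    ages = sorted(series)
    n = len(ages)
    if n < 2:
        raise ValidationError("smoothing needs at least two ages")
    if not 1 <= edf <= n:
        raise ValidationError(f"edf must lie in [1, {n}], got {edf}")
    if edf == n:
        return {a: series[a] for a in ages}
    out: dict[int, dict[str, float]] = {a: {} for a in ages}
    x = np.asarray(ages, dtype=float)
    for name in ("lam", "mu", "sigma"):
        yvals = np.array([getattr(series[a], name) for a in ages])
        poly = np.polynomial.Polynomial.fit(x, yvals, deg=edf - 1)
        fitted = poly(x)
        for a, v in zip(ages, fitted):
            out[a][name] = float(v)
    return {a: LMSTriple(**out[a]) for a in ages}


def build_reference(
    cohort: pd.DataFrame, options: BuildOptions | None = None
) -> PercentileTable:
    """Fit the full reference grid and evaluate its percentile columns.

    Deterministic for a given cohort and options.  With
    ``options.params_override`` supplying a triple for a cell, that cell's
    fit is bypassed — used to render tables from already-published
    parameters.
    """
    opts = options or BuildOptions()
    pct_sets = opts.resolved_percentile_sets()
    groups = stratify(cohort, opts.age_window)
    lo, hi = opts.age_window
    ages = range(lo, hi + 1)
    override = dict(opts.params_override or {})

    triples: dict[tuple[str, int, str], LMSTriple] = {}
    sizes: dict[tuple[str, int, str], int] = {}
    for sex in opts.sexes:
        for age in ages:
            for measure in MEASURES:
                key = (sex, age, measure)
                values = groups.get(key, np.empty(0))
                sizes[key] = int(values.size)
                if key in override:
                    triples[key] = override[key]
                    continue
                if values.size < opts.fit.min_group_size:
                    if opts.skip_unfittable:
                        log.warning("skipping unfittable group %s (n=%d)", key, values.size)
                        continue
                    raise ValidationError(
                        f"group {key} has {values.size} records, below the minimum "
                        f"{opts.fit.min_group_size}; set skip_unfittable to proceed"
                    )
                try:
                    triples[key] = fit_group(
                        MeasurementSample(values, measure=measure), opts.fit
                    )
                except GrowthRefError as exc:
                    raise type(exc)(f"group {key}: {exc}") from exc

    if opts.smoothing_edf is not None:
        smoothed: dict[tuple[str, int, str], LMSTriple] = {}
        for sex in opts.sexes:
            for measure in MEASURES:
                per_age = {
                    age: triples[(sex, age, measure)]
                    for age in ages
                    if (sex, age, measure) in triples
                }
                if len(per_age) >= 2:
                    for age, t in smooth_series(per_age, opts.smoothing_edf).items():
                        smoothed[(sex, age, measure)] = t
                else:
                    smoothed.update(
                        {(sex, a, measure): t for a, t in per_age.items()}
                    )
        triples = smoothed

    rows = []
    for sex in opts.sexes:
        for age in ages:
            for measure in MEASURES:
                key = (sex, age, measure)
                if key not in triples:
                    continue
                params = triples[key]
                pcts = {
                    spec.label: centile(params, spec) for spec in pct_sets[measure]
                }
                rows.append(
                    ReferenceRow(
                        sex=sex,
                        age_group=age,
                        measure=measure,
                        params=params,
                        percentiles=pcts,
                        n=sizes.get(key) or None,
                    )
                )
    provenance = {
        "age_window": list(opts.age_window),
        "smoothing_edf": opts.smoothing_edf,
        "min_group_size": opts.fit.min_group_size,
        "n_records": int(len(cohort)),
    }
    return PercentileTable(rows=rows, percentile_sets=pct_sets, provenance=provenance)


def median_growth_summary(table: PercentileTable) -> pd.DataFrame:
    """Per-sex, per-measure change in the median between boundary ages.

    Returns ``P50(max age) - P50(min age)`` in measurement units; a table
    with a single age yields zero growth flagged by ``single_age``.
    """
    records = []
    sexes = sorted({row.sex for row in table.rows})
    measures = [m for m in MEASURES if any(r.measure == m for r in table.rows)]
    for sex in sexes:
        for measure in measures:
            series = table.p50_series(sex, measure)
            if not series:
                continue
            first_age, last_age = min(series), max(series)
            if first_age == last_age:
                log.warning("growth summary: single age %s for %s/%s", first_age, sex, measure)
            for boundary in (first_age, last_age):
                if boundary not in series:
                    raise DomainError(f"missing boundary age {boundary} for {sex}/{measure}")
            records.append(
                {
                    "sex": sex,
                    "measure": measure,
                    "first_age": first_age,
                    "last_age": last_age,
                    "p50_first": series[first_age],
                    "p50_last": series[last_age],
                    "median_growth": series[last_age] - series[first_age],
                    "single_age": first_age == last_age,
                }
            )
    return pd.DataFrame(records)
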
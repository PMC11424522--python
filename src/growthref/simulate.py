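"""Synthetic adolescent cohorts with the distributional structure the
reference pipeline assumes.

Within each (sex, completed-year age) cell, height and weight are drawn
from Box-Cox-normal distributions under a stated LMS parameter table by
inverting the LMS transform on standard-normal draws; the two z-draws
share a Gaussian-copula correlation (physiologically, taller children
tend to be heavier), and BMI is derived arithmetically from the sampled
height and weight.  The module also emulates the stratified
schools-within-strata sampling design and implements the standard
cluster-survey sample-size formula ``n = Z^2 P Q / e^2 * D``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .lms import LAM_EPS, LMSTriple
from .reference import compute_bmi

__all__ = [
    "CohortSpec",
    "SampleSizeSpec",
    "generate_cohort",
    "emulate_sampling_design",
    "sample_size",
    "default_cohort_spec",
]

#: per-cell cap on the Box-Cox positivity rejection rate; a higher rate
#: means the stated parameters put visible mass outside the support
MAX_REJECTION_RATE = 0.01

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class CohortSpec:
    """Generating conditions for one synthetic cohort.

    ``lms_table`` maps (sex, age, measure) to the generating
    :class:`~growthref.lms.LMSTriple`; height and weight triples are
    required for every (sex, age) cell.  In ``derive_from_hw`` mode BMI is
    computed from the sampled height and weight (arithmetically consistent
    records); in ``independent_lms`` mode BMI is drawn from its own triple
    (distributionally faithful to a published BMI table, but no longer
    equal to weight/height^2 record by record).
    """

    lms_table: Mapping[tuple[str, int, str], LMSTriple]
    n_per_cell: int = 297
    sexes: tuple[str, ...] = ("male", "female")
    ages: tuple[int, ...] = (12, 13, 14, 15, 16)
    seed: int | None = None
    bmi_mode: str = "derive_from_hw"
    hw_correlation: float = 0.5

    def __post_init__(self) -> None:
        if self.n_per_cell < 0:
            raise ValidationError("n_per_cell must be nonnegative")
        if self.bmi_mode not in ("derive_from_hw", "independent_lms"):
            raise ValidationError(f"unknown bmi_mode {self.bmi_mode!r}")
        if not -1.0 < self.hw_correlation < 1.0:
            raise ValidationError("hw_correlation must lie in (-1, 1)")
        needed = ["height", "weight"]
        if self.bmi_mode == "independent_lms":
            needed.append("bmi")
        for sex in self.sexes:
            for age in self.ages:
                for measure in needed:
                    if (sex, age, measure) not in self.lms_table:
                        raise ValidationError(
                            f"lms_table is missing a {measure} triple for ({sex}, {age})"
                        )


def _invert_lms(z: np.ndarray, params: LMSTriple) -> np.ndarray:
    """Measurement values whose LMS z-scores are ``z`` (valid z only)."""
    if abs(params.lam) < LAM_EPS:
        return params.mu * np.exp(params.sigma * z)
    return params.mu * np.exp(np.log1p(params.lam * params.sigma * z) / params.lam)


def _valid_z(z: np.ndarray, params: LMSTriple) -> np.ndarray:
    if abs(params.lam) < LAM_EPS:
        return np.ones_like(z, dtype=bool)
    return 1.0 + params.lam * params.sigma * z > 0.0


def _draw_cell_z(
    rng: np.random.Generator,
    n: int,
    triples: Sequence[LMSTriple],
    corr: np.ndarray,
    cell: tuple,
) -> np.ndarray:
    """Correlated standard-normal draws, redrawing rows that violate the
    Box-Cox positivity constraint for any of the cell's measures.

    Raises if the first-pass rejection rate exceeds the 1% cap: silent
    truncation would bias downstream parameter-recovery checks.
    """
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, len(triples))) @ chol.T
    bad = ~np.logical_and.reduce([_valid_z(z[:, j], t) for j, t in enumerate(triples)])
    rate = float(bad.mean()) if n else 0.0
    if rate > MAX_REJECTION_RATE:
        raise DomainError(
            f"cell {cell}: positivity rejection rate {rate:.2%} exceeds "
            f"{MAX_REJECTION_RATE:.0%}; generating parameters are implausible"
        )
    for _ in range(_MAX_REDRAWS):
        if not bad.any():
            return z
        k = int(bad.sum())
        z[bad] = rng.standard_normal((k, len(triples))) @ chol.T
        bad = ~np.logical_and.reduce(
            [_valid_z(z[:, j], t) for j, t in enumerate(triples)]
        )
    raise DomainError(f"cell {cell}: rejection sampling failed to terminate")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort; fully reproducible for a given spec and seed.

    Returns a DataFrame with columns ``id, sex, age_years, age_group,
    height_cm, weight_kg, bmi``.  Ages are uniform within the completed
    year (the reference model treats age as integer groups).
    """
    if spec.seed is None:
        raise ValidationError("CohortSpec.seed must be set for reproducibility")
    rng = np.random.default_rng(spec.seed)
    rho = spec.hw_correlation
    frames = []
    subject = 0
    for sex in spec.sexes:
        for age in spec.ages:
            n = spec.n_per_cell
            if n == 0:
                continue
            h_t = spec.lms_table[(sex, age, "height")]
            w_t = spec.lms_table[(sex, age, "weight")]
            if spec.bmi_mode == "independent_lms":
                b_t = spec.lms_table[(sex, age, "bmi")]
                triples = (h_t, w_t, b_t)
                corr = np.array([[1.0, rho, 0.0], [rho, 1.0, 0.0], [0.0, 0.0, 1.0]])
            else:
                triples = (h_t, w_t)
                corr = np.array([[1.0, rho], [rho, 1.0]])
            z = _draw_cell_z(rng, n, triples, corr, (sex, age))
            height = _invert_lms(z[:, 0], h_t)
            weight = _invert_lms(z[:, 1], w_t)
            if spec.bmi_mode == "independent_lms":
                bmi = _invert_lms(z[:, 2], triples[2])
            else:
                bmi = weight / (height / 100.0) ** 2
            age_years = age + rng.uniform(0.0, 1.0, size=n)
            ids = [f"S{subject + i:06d}" for i in range(n)]
            subject += n
            frames.append(
                pd.DataFrame(
                    {
                        "id": ids,
                        "sex": sex,
                        "age_years": age_years,
                        "age_group": age,
                        "height_cm": height,
                        "weight_kg": weight,
                        "bmi": bmi,
                    }
                )
            )
    columns = ["id", "sex", "age_years", "age_group", "height_cm", "weight_kg", "bmi"]
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)[columns]


def emulate_sampling_design(
    schools_per_stratum: int = 20,
    students_per_school: int = 50,
    strata: Sequence[str] | int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cluster labels for a stratified schools-within-strata design.

    Returns one row per sampled student with ``stratum``, ``school`` and
    ``student`` labels (defaults: 3 strata x 20 schools x 50 students =
    3,000 rows, 60 distinct schools).  Row order is a seeded shuffle so
    labels can be zipped onto generated records; the labels never alter
    measurement distributions.
    """
    if isinstance(strata, int):
        if strata <= 0:
            raise ValidationError("strata count must be positive")
        strata = [f"stratum_{i + 1}" for i in range(strata)]
    if schools_per_stratum <= 0 or students_per_school <= 0:
        raise ValidationError("school and student counts must be positive")
    records = []
    school_no = 0
    for stratum in strata:
        for _ in range(schools_per_stratum):
            school_no += 1
            school = f"school_{school_no:03d}"
            for s in range(students_per_school):
                records.append(
                    {"stratum": stratum, "school": school, "student": s + 1}
                )
    frame = pd.DataFrame(records, columns=["stratum", "school", "student"])
    if seed is not None:
        rng = np.random.default_rng(seed)
        frame = frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)
    return frame


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to the cluster-survey sample-size formula.

    ``P`` is the anticipated proportion, ``Z`` the normal deviate of the
    confidence level, ``e`` the precision, ``D`` the design effect; ``Q``
    is always ``1 - P``.
    """

    P: float
    Z: float = 1.96
    e: float = 0.05
    D: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.P < 1.0:
            raise ValidationError(f"P must lie in (0, 1), got {self.P}")
        if not self.Z > 0:
            raise ValidationError("Z must be positive")
        if not self.e > 0:
            raise ValidationError("e must be positive")
        if not self.D >= 1:
            raise ValidationError("design effect D must be >= 1")

    @property
    def Q(self) -> float:
        return 1.0 - self.P


def sample_size(spec: SampleSizeSpec) -> int:
    """Required sample size ``ceil(Z^2 P Q / e^2 * D)``."""
    raw = spec.Z**2 * spec.P * spec.Q / spec.e**2 * spec.D
    return int(math.ceil(raw))


def default_cohort_spec(seed: int, n_per_cell: int = 297, **kwargs) -> CohortSpec:
    """Cohort spec using the packaged published LMS table as generator.

    Defaults mirror the study design the package emulates: ages 12-16,
    both sexes, 297 subjects per cell (2,970 in total).
    """
    from .datasets import load_published_reference

    table = load_published_reference()
    lms_table = {
        (row.sex, row.age_group, row.measure): row.params for row in table.rows
    }
    return CohortSpec(
        lms_table=lms_table, n_per_cell=n_per_cell, seed=seed, **kwargs
    )
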
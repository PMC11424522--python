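"""The Box-Cox Cole-Green (LMS) distribution and its maximum-likelihood fit.

The LMS method summarises a positive, possibly skewed measurement
distribution (height, weight, BMI within one age-sex cell) by three
parameters: the Box-Cox power ``L`` (lambda) that removes skewness, the
median ``M`` (mu), and the coefficient of variation ``S`` (sigma).  For
``L != 0`` the transformed measurement

    Z = ((Y / M)**L - 1) / (L * S)

is standard normal, with the log-form limit ``Z = ln(Y/M) / S`` at
``L == 0``.  Every centile and z-score then has a closed form, and the
three parameters can be estimated per cell by maximising the implied
log-likelihood.

The positivity truncation term of the Box-Cox normal density is omitted,
the standard Cole-Green practice: for ``S`` well below ``1/|L*z|`` over
the centile range of interest the truncated mass is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ConvergenceError, DomainError, ValidationError

__all__ = [
    "LMSTriple",
    "PercentileSpec",
    "MeasurementSample",
    "FitOptions",
    "centile",
    "zscore",
    "loglikelihood",
    "fit_group",
    "round_half_away",
    "HEIGHT_WEIGHT_PERCENTILES",
    "BMI_PERCENTILES",
]

#: below this magnitude the Box-Cox power is treated as exactly zero
#: (log-normal limit); keeps the transform continuous at L = 0
LAM_EPS = 1e-7

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (published-table rendering).

    Internal computation is never rounded; this is display arithmetic only.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class LMSTriple:
    """One age-sex-measure cell's Box-Cox power L, median M and CV S.

    ``lam`` is unitless and may be negative or zero; ``mu`` is in
    measurement units (cm, kg or kg/m^2) and must be positive; ``sigma``
    is the unitless coefficient of variation, positive and in practice
    well below 1.
    """

    lam: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lam", _require_finite("lam", self.lam))
        object.__setattr__(self, "mu", _require_finite("mu", self.mu))
        object.__setattr__(self, "sigma", _require_finite("sigma", self.sigma))
        if self.mu <= 0:
            raise ValidationError(f"mu must be positive, got {self.mu}")
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be positive, got {self.sigma}")

    @property
    def is_log_form(self) -> bool:
        return abs(self.lam) < LAM_EPS

    def supports(self, z: float) -> bool:
        """Whether the Box-Cox argument 1 + L*S*z stays positive at ``z``."""
        return self.is_log_form or 1.0 + self.lam * self.sigma * z > 0.0


def _default_label(p: float) -> str:
    pct = 100.0 * p
    if math.isclose(pct, round(pct), abs_tol=1e-9):
        return f"P{int(round(pct))}"
    return f"P{pct:g}"


@dataclass(frozen=True)
class PercentileSpec:
    """A probability with its full-precision normal quantile and label.

    ``z`` is always derived from ``p`` through the inverse standard-normal
    distribution function at floating precision — never from a two-digit
    lookup, because published table cells only reproduce with the exact
    quantile.
    """

    p: float
    z: float
    label: str

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValidationError(f"p must lie in (0, 1), got {self.p}")
        expected = float(stats.norm.ppf(self.p))
        if abs(self.z - expected) > 1e-10:
            raise ValidationError(
                f"z={self.z!r} is not the normal quantile of p={self.p!r}"
            )

    @classmethod
    def from_p(cls, p: float, label: str | None = None) -> "PercentileSpec":
        p = float(p)
        if not 0.0 < p < 1.0:
            raise ValidationError(f"p must lie in (0, 1), got {p}")
        z = 0.0 if p == 0.5 else float(stats.norm.ppf(p))
        return cls(p=p, z=z, label=label or _default_label(p))

    @classmethod
    def from_label(cls, label: str) -> "PercentileSpec":
        """Parse labels such as ``P3``, ``P50`` or ``P97.5``."""
        if not label.startswith("P"):
            raise ValidationError(f"percentile label must start with 'P': {label!r}")
        try:
            pct = float(label[1:])
        except ValueError as exc:
            raise ValidationError(f"cannot parse percentile label {label!r}") from exc
        return cls.from_p(pct / 100.0, label=label)


#: Table layout used for height and weight references
HEIGHT_WEIGHT_PERCENTILES: tuple[PercentileSpec, ...] = tuple(
    PercentileSpec.from_p(p / 100.0) for p in (3, 10, 35, 50, 65, 90)
)
#: Table layout used for BMI references
BMI_PERCENTILES: tuple[PercentileSpec, ...] = tuple(
    PercentileSpec.from_p(p / 100.0) for p in (5, 15, 50, 85, 90, 95)
)


@dataclass(frozen=True)
class MeasurementSample:
    """The strictly positive measurements of one age-sex-measure cell."""

    values: np.ndarray
    measure: str = "measurement"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            values = values.ravel()
        if values.size == 0:
            raise ValidationError("sample must be nonempty")
        if not np.all(np.isfinite(values)):
            raise ValidationError(f"{self.measure}: sample contains non-finite values")
        if np.any(values <= 0):
            raise ValidationError(f"{self.measure}: all values must be positive")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)


def _as_spec(spec) -> PercentileSpec:
    if isinstance(spec, PercentileSpec):
        return spec
    return PercentileSpec.from_p(float(spec))


def centile(params: LMSTriple, spec) -> float:
    """The ``p``-th percentile of the cell's distribution.

    ``spec`` may be a :class:`PercentileSpec` or a bare probability.
    Strictly increasing in ``p`` and equal to ``mu`` at ``p = 0.5``.
    """
    spec = _as_spec(spec)
    if spec.p == 0.5:
        return params.mu
    z = spec.z
    if params.is_log_form:
        return params.mu * math.exp(params.sigma * z)
    t = params.lam * params.sigma * z
    if t <= -1.0:
        raise DomainError(
            f"Box-Cox argument 1 + L*S*z = {1.0 + t:.6g} <= 0 at {spec.label} "
            f"(L={params.lam}, S={params.sigma}): percentile outside the "
            "distribution's support"
        )
    # (1 + t)**(1/L) via log1p: no cancellation as L -> 0
    return params.mu * math.exp(math.log1p(t) / params.lam)


def zscore(y, params: LMSTriple):
    """z-score of measurement ``y`` under ``params``; exact inverse of centile.

    Accepts a scalar or an array; all values must be strictly positive.
    """
    arr = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("measurement must be finite")
    if np.any(arr <= 0):
        raise DomainError("measurement must be strictly positive")
    ratio = arr / params.mu
    if params.is_log_form:
        out = np.log(ratio) / params.sigma
    else:
        out = np.expm1(params.lam * np.log(ratio)) / (params.lam * params.sigma)
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def _loglik_terms(y: np.ndarray, lam: float, mu: float, sigma: float) -> np.ndarray:
    log_ratio = np.log(y / mu)
    if abs(lam) < LAM_EPS:
        z = log_ratio / sigma
    else:
        z = np.expm1(lam * log_ratio) / (lam * sigma)
    return (lam - 1.0) * np.log(y) - lam * math.log(mu) - math.log(sigma) \
        - _LOG_SQRT_2PI - 0.5 * z * z


def loglikelihood(sample: MeasurementSample, params: LMSTriple) -> float:
    """Box-Cox Cole-Green log-likelihood of ``sample`` at ``params``.

    Additive over observations and invariant under reordering; the
    positivity truncation term is omitted (see module docstring).
    """
    if not isinstance(sample, MeasurementSample):
        sample = MeasurementSample(np.asarray(sample, dtype=float))
    return float(np.sum(_loglik_terms(sample.values, params.lam, params.mu, params.sigma)))


@dataclass(frozen=True)
class FitOptions:
    """Controls for the per-cell maximum-likelihood fit.

    Bounds keep the optimiser inside the region where the distribution is
    well behaved; the start point ``(lam=1, mu=median, sigma=sd/mean)``
    corresponds to a plain normal first guess.
    """

    lam_bounds: tuple[float, float] = (-5.0, 7.0)
    sigma_bounds: tuple[float, float] = (1e-4, 1.0)
    mu_bounds: tuple[float, float] | None = None  # default: data-driven
    min_group_size: int = 20
    max_iterations: int = 20000
    xatol: float = 1e-8
    fatol: float = 1e-10


def fit_group(sample: MeasurementSample, options: FitOptions | None = None) -> LMSTriple:
    """Maximum-likelihood LMS fit for one cell.

    Deterministic: fixed start point, bounded Nelder-Mead simplex search
    followed by a restart from the first optimum to polish it.  Raises
    :class:`ConvergenceError` (carrying the last iterate) if the simplex
    does not converge, and :class:`ValidationError` for degenerate or
    undersized samples.
    """
    if not isinstance(sample, MeasurementSample):
        sample = MeasurementSample(np.asarray(sample, dtype=float))
    opts = options or FitOptions()
    # sorted copy: the likelihood is order-invariant, and a canonical order
    # makes the fit bitwise identical under permutation of the sample
    y = np.sort(sample.values)
    if len(sample) < opts.min_group_size:
        raise ValidationError(
            f"{sample.measure}: group size {len(sample)} is below the "
            f"configured minimum {opts.min_group_size}"
        )
    if np.ptp(y) == 0.0:
        raise ValidationError(f"{sample.measure}: degenerate sample (all values equal)")

    mu0 = float(np.median(y))
    sigma0 = float(np.std(y) / np.mean(y))
    lo_s, hi_s = opts.sigma_bounds
    sigma0 = min(max(sigma0, lo_s * 1.01), hi_s * 0.99)
    mu_bounds = opts.mu_bounds or (0.2 * float(np.min(y)), 5.0 * float(np.max(y)))
    bounds = optimize.Bounds(
        [opts.lam_bounds[0], mu_bounds[0], lo_s],
        [opts.lam_bounds[1], mu_bounds[1], hi_s],
    )

    def negloglik(theta: np.ndarray) -> float:
        lam, mu, sigma = theta
        if mu <= 0 or sigma <= 0:
            return np.inf
        return -float(np.sum(_loglik_terms(y, lam, mu, sigma)))

    x0 = np.array([1.0, mu0, sigma0])
    result = None
    for _ in range(2):  # restart once from the optimum to polish
        result = optimize.minimize(
            negloglik,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "maxiter": opts.max_iterations,
                "xatol": opts.xatol,
                "fatol": opts.fatol,
            },
        )
        x0 = result.x
    if not result.success:
        raise ConvergenceError(
            f"{sample.measure}: LMS fit did not converge ({result.message})",
            last_iterate=tuple(result.x),
        )
    lam, mu, sigma = result.x
    return LMSTriple(lam=float(lam), mu=float(mu), sigma=float(sigma))
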
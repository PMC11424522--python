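"""Compare a local reference's medians with external reference standards.

External references (WHO, US-CDC, national studies) provide per-age
median values only; the comparison reports ``local - external`` per
overlapping (sex, age, measure) key and min/max/mean differences per
source, sex and measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import DomainError, ValidationError
from .reference import PercentileTable

__all__ = ["ExternalReference", "ReferenceComparison", "compare_medians"]

log = logging.getLogger(__name__)

ROW_COLUMNS = ["source", "sex", "measure", "age", "local_p50", "external_p50", "difference"]
SUMMARY_COLUMNS = ["source", "sex", "measure", "min_difference", "max_difference", "mean_difference"]

#: local/external median ratio beyond which a unit mismatch is suspected
_UNIT_GUARD = 3.0


@dataclass(frozen=True)
class ExternalReference:
    """One external source's median table keyed by (sex, age, measure).

    Cells the source does not publish are simply absent from ``medians``
    (never encoded as zero).
    """

    name: str
    medians: dict[tuple[str, int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (sex, age, measure), value in self.medians.items():
            if not isinstance(age, int):
                raise ValidationError(f"{self.name}: ages must be integers, got {age!r}")
            if not value > 0:
                raise ValidationError(
                    f"{self.name}: median for {(sex, age, measure)} must be positive"
                )


@dataclass
class ReferenceComparison:
    """Per-key differences and per-source summary extremes."""

    rows: pd.DataFrame
    summaries: pd.DataFrame


def compare_medians(
    local: PercentileTable, externals: list[ExternalReference] | ExternalReference
) -> ReferenceComparison:
    """Difference ``local P50 - external P50`` over overlapping keys.

    Missing external cells are skipped with a log entry; zero overlap is
    an error, and a gross local/external ratio (>3x either way) raises a
    unit-mismatch error.
    """
    if isinstance(externals, ExternalReference):
        externals = [externals]
    local_medians = {
        (row.sex, row.age_group, row.measure): row.params.mu for row in local.rows
    }
    records = []
    for ext in externals:
        matched = 0
        for key, local_value in sorted(local_medians.items()):
            if key not in ext.medians:
                log.debug("comparison: %s has no median for %s", ext.name, key)
                continue
            ext_value = ext.medians[key]
            ratio = local_value / ext_value
            if ratio > _UNIT_GUARD or ratio < 1.0 / _UNIT_GUARD:
                raise ValidationError(
                    f"{ext.name}: suspected unit mismatch at {key} "
                    f"(local {local_value:.4g} vs external {ext_value:.4g})"
                )
            matched += 1
            sex, age, measure = key
            records.append(
                {
                    "source": ext.name,
                    "sex": sex,
                    "measure": measure,
                    "age": age,
                    "local_p50": local_value,
                    "external_p50": ext_value,
                    "difference": local_value - ext_value,
                }
            )
        if matched == 0:
            log.warning("comparison: no overlap with source %s", ext.name)
    if not records:
        raise DomainError("no overlapping (sex, age, measure) keys with any source")
    rows = pd.DataFrame(records, columns=ROW_COLUMNS)
    summaries = (
        rows.groupby(["source", "sex", "measure"], sort=True)["difference"]
        .agg(min_difference="min", max_difference="max", mean_difference="mean")
        .reset_index()
    )
    return ReferenceComparison(rows=rows, summaries=summaries[SUMMARY_COLUMNS])
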
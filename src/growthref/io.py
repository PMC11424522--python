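"""Delimited-text readers and writers for every pipeline artifact.

One dialect throughout: comma-separated, UTF-8, header required, ``.``
decimal separator.  Provenance (seed, config echo, package version) is
embedded as ``#`` comment lines, which every reader skips.  Sex codes are
``male``/``female``, case-insensitive on read and canonical on write.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .compare import ExternalReference, ReferenceComparison
from .errors import SchemaError, ValidationError
from .lms import LMSTriple, PercentileSpec, round_half_away
from .reference import MEASURES, SEXES, PercentileTable, ReferenceRow, compute_bmi
from .validation import ROW_COLUMNS, SUMMARY_COLUMNS, ValidationReport

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_percentile_table",
    "write_percentile_table",
    "read_validation_report",
    "write_validation_report",
    "read_external_references",
    "write_comparison",
]

log = logging.getLogger(__name__)

COHORT_COLUMNS = ["id", "sex", "age_years", "height_cm", "weight_kg"]

_TABLE_FIXED = ["sex", "age_group", "measure", "n", "lam", "mu", "sigma"]


def _write_comments(handle, provenance: Mapping | None) -> None:
    if provenance:
        for key, value in provenance.items():
            handle.write(f"# {key}={value}\n")


def _read_comments(path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_cohort(path, max_reject_fraction: float = 0.10) -> pd.DataFrame:
    """Read and validate a cohort file; derive BMI and completed-year age.

    Rows failing validation are dropped with per-reason counts logged; if
    more than ``max_reject_fraction`` of rows are rejected the file is
    considered broken and a hard error is raised.  BMI is always
    recomputed from height and weight, never trusted from the input.
    """
    raw = pd.read_csv(path, comment="#", dtype={"id": str}, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"cohort file {path} is missing columns: {missing}")

    reasons: Counter[str] = Counter()
    sex = raw["sex"].astype(str).str.strip().str.lower()
    bad_sex = ~sex.isin(SEXES)
    numeric = {
        col: pd.to_numeric(raw[col], errors="coerce")
        for col in ("age_years", "height_cm", "weight_kg")
    }
    bad_age = numeric["age_years"].isna() | (numeric["age_years"] < 0)
    bad_height = numeric["height_cm"].isna() | (numeric["height_cm"] <= 0)
    bad_weight = numeric["weight_kg"].isna() | (numeric["weight_kg"] <= 0)
    reasons["unknown_sex"] = int(bad_sex.sum())
    reasons["bad_age"] = int(bad_age.sum())
    reasons["nonpositive_or_missing_height"] = int(bad_height.sum())
    reasons["nonpositive_or_missing_weight"] = int(bad_weight.sum())
    bad = bad_sex | bad_age | bad_height | bad_weight
    n_bad = int(bad.sum())
    if n_bad:
        log.warning(
            "read_cohort: rejected %d/%d rows (%s)",
            n_bad,
            len(raw),
            {k: v for k, v in reasons.items() if v},
        )
    if len(raw) and n_bad / len(raw) > max_reject_fraction:
        raise ValidationError(
            f"{path}: {n_bad}/{len(raw)} rows rejected, above the "
            f"{max_reject_fraction:.0%} tolerance"
        )
    frame = pd.DataFrame(
        {
            "id": raw["id"],
            "sex": sex,
            "age_years": numeric["age_years"],
            "height_cm": numeric["height_cm"],
            "weight_kg": numeric["weight_kg"],
        }
    )[~bad].reset_index(drop=True)
    frame["age_group"] = np.floor(frame["age_years"]).astype(int)
    frame["bmi"] = frame["weight_kg"] / (frame["height_cm"] / 100.0) ** 2
    return frame[["id", "sex", "age_years", "age_group", "height_cm", "weight_kg", "bmi"]]


def write_cohort(cohort: pd.DataFrame, path, provenance: Mapping | None = None) -> None:
    """Write the canonical five-column cohort schema (BMI is derived, not stored)."""
    with open(path, "w", encoding="utf-8") as handle:
        _write_comments(handle, provenance)
        cohort[COHORT_COLUMNS].to_csv(handle, index=False)


def write_percentile_table(
    table: PercentileTable, path, provenance: Mapping | None = None
) -> None:
    """Write a reference table: L/M/S at full precision, percentile cells as
    the published two-decimal display columns."""
    frame = table.to_frame()
    labels = [c for c in frame.columns if c not in _TABLE_FIXED]
    with open(path, "w", encoding="utf-8") as handle:
        _write_comments(handle, {**table.provenance, **(provenance or {})})
        handle.write(",".join(_TABLE_FIXED + labels) + "\n")
        for _, row in frame.iterrows():
            n = "" if pd.isna(row["n"]) or row["n"] is None else str(int(row["n"]))
            cells = [
                str(row["sex"]),
                str(int(row["age_group"])),
                str(row["measure"]),
                n,
                repr(float(row["lam"])),
                repr(float(row["mu"])),
                repr(float(row["sigma"])),
            ]
            for label in labels:
                value = row[label]
                cells.append(
                    "" if pd.isna(value) else f"{round_half_away(value, 2):.2f}"
                )
            handle.write(",".join(cells) + "\n")


def read_percentile_table(path) -> PercentileTable:
    """Read a reference table written by :func:`write_percentile_table`.

    The percentile set of each measure is inferred from the columns its
    rows populate; L/M/S round-trip bit-exactly.
    """
    try:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"cannot parse percentile table {path}: {exc}") from exc
    missing = [c for c in _TABLE_FIXED if c not in frame.columns]
    if missing:
        raise SchemaError(f"percentile table {path} is missing columns: {missing}")
    labels = [c for c in frame.columns if c not in _TABLE_FIXED]
    specs = {label: PercentileSpec.from_label(label) for label in labels}
    ordered = sorted(labels, key=lambda c: specs[c].p)

    rows: list[ReferenceRow] = []
    sets: dict[str, tuple[PercentileSpec, ...]] = {}
    for i, rec in frame.iterrows():
        try:
            params = LMSTriple(float(rec["lam"]), float(rec["mu"]), float(rec["sigma"]))
            present = [c for c in ordered if not pd.isna(rec[c])]
            percentiles = {c: float(rec[c]) for c in present}
            n = None if pd.isna(rec["n"]) else int(rec["n"])
            row = ReferenceRow(
                sex=str(rec["sex"]).strip().lower(),
                age_group=int(rec["age_group"]),
                measure=str(rec["measure"]).strip().lower(),
                params=params,
                percentiles=percentiles,
                n=n,
            )
        except (ValueError, ValidationError) as exc:
            raise SchemaError(f"{path}: malformed row at line {i + 2}: {exc}") from exc
        rows.append(row)
        sets.setdefault(row.measure, tuple(specs[c] for c in present))
    return PercentileTable(rows=rows, percentile_sets=sets, provenance=_read_comments(path))


def write_validation_report(
    report: ValidationReport, path, provenance: Mapping | None = None
) -> None:
    """Serialize a back-substitution report in the published-table layout.

    Per-cell rows carry actual/fitted P50, the unrounded signed relative
    error and its two-decimal rendering; summary rows carry the mean
    signed error, the true MAPE (%) and the Lewis class.
    """
    rows = report.rows.copy()
    rows["record_type"] = "row"
    rows["printed_error"] = rows["signed_rel_error"].map(lambda e: f"{round_half_away(e, 2):.2f}")
    summaries = report.summaries.copy()
    summaries["record_type"] = "summary"
    combined = pd.concat([rows, summaries], ignore_index=True)
    columns = (
        ["record_type"]
        + ROW_COLUMNS
        + ["printed_error"]
        + [c for c in SUMMARY_COLUMNS if c not in ROW_COLUMNS]
    )
    combined = combined.reindex(columns=columns)
    with open(path, "w", encoding="utf-8") as handle:
        _write_comments(
            handle,
            {"fraction": report.fraction, "seed": report.seed, **(provenance or {})},
        )
        combined.to_csv(handle, index=False)


def read_validation_report(path) -> ValidationReport:
    """Round-trip reader for :func:`write_validation_report` output."""
    meta = _read_comments(path)
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "record_type" not in frame.columns:
        raise SchemaError(f"{path}: not a validation report (no record_type column)")
    rows = frame[frame["record_type"] == "row"][ROW_COLUMNS].copy()
    rows["age"] = rows["age"].astype(int)
    summaries = frame[frame["record_type"] == "summary"][SUMMARY_COLUMNS].copy()
    seed = meta.get("seed")
    return ValidationReport(
        rows=rows.reset_index(drop=True),
        summaries=summaries.reset_index(drop=True),
        fraction=float(meta.get("fraction", "nan")),
        seed=None if seed in (None, "None") else int(seed),
    )


def read_external_references(path) -> list[ExternalReference]:
    """Read external median tables: columns source, sex, age, measure, p50."""
    frame = pd.read_csv(path, comment="#")
    required = ["source", "sex", "age", "measure", "p50"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"external reference file {path} is missing columns: {missing}")
    out = []
    for source, sub in frame.groupby("source", sort=True):
        medians: dict[tuple[str, int, str], float] = {}
        for _, rec in sub.iterrows():
            key = (
                str(rec["sex"]).strip().lower(),
                int(rec["age"]),
                str(rec["measure"]).strip().lower(),
            )
            if key in medians:
                raise ValidationError(f"{source}: duplicate key {key} in {path}")
            medians[key] = float(rec["p50"])
        out.append(ExternalReference(name=str(source), medians=medians))
    return out


def write_comparison(
    comparison: ReferenceComparison, path, provenance: Mapping | None = None
) -> None:
    """Serialize a median comparison (per-key rows plus per-source extremes)."""
    rows = comparison.rows.copy()
    rows["record_type"] = "row"
    summaries = comparison.summaries.copy()
    summaries["record_type"] = "summary"
    combined = pd.concat([rows, summaries], ignore_index=True)
    lead = ["record_type", "source", "sex", "measure"]
    combined = combined.reindex(
        columns=lead + [c for c in combined.columns if c not in lead]
    )
    with open(path, "w", encoding="utf-8") as handle:
        _write_comments(handle, provenance)
        combined.to_csv(handle, index=False)
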
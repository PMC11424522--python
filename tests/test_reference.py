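"""Reference construction: stratification, fitting, smoothing, summaries."""

import numpy as np
import pandas as pd
import pytest

from growthref import (
    BuildOptions,
    DomainError,
    FitOptions,
    LMSTriple,
    ValidationError,
    build_reference,
    centile,
    compute_bmi,
    median_growth_summary,
    smooth_series,
    stratify,
)
from growthref.reference import records_to_frame, AnthropometricRecord


def small_cohort(rng, triples, n, sexes=("male",), ages=(12,)):
    """Cohort drawn directly from LMS triples (log1p-free inverse form)."""
    frames = []
    sid = 0
    for sex in sexes:
        for age in ages:
            h = triples[(sex, age, "height")]
            w = triples[(sex, age, "weight")]
            zh = rng.standard_normal(n)
            zw = rng.standard_normal(n)
            # drop the rare draws outside the Box-Cox support
            keep = (1 + h.lam * h.sigma * zh > 0) & (1 + w.lam * w.sigma * zw > 0)
            zh, zw = zh[keep], zw[keep]
            n = int(keep.sum())
            height = h.mu * (1 + h.lam * h.sigma * zh) ** (1 / h.lam)
            weight = w.mu * (1 + w.lam * w.sigma * zw) ** (1 / w.lam)
            frames.append(
                pd.DataFrame(
                    {
                        "id": [f"S{sid + i}" for i in range(n)],
                        "sex": sex,
                        "age_years": age + rng.uniform(0, 1, n),
                        "age_group": age,
                        "height_cm": height,
                        "weight_kg": weight,
                        "bmi": weight / (height / 100) ** 2,
                    }
                )
            )
            sid += n
    return pd.concat(frames, ignore_index=True)


class TestComputeBmi:
    def test_direct_arithmetic(self):
        assert compute_bmi(50, 160) == pytest.approx(19.53125)
        assert compute_bmi(80, 200) == pytest.approx(20.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            compute_bmi(0, 160)
        with pytest.raises(ValidationError):
            compute_bmi(50, -1)


class TestRecords:
    def test_record_derives_bmi_and_age_group(self):
        rec = AnthropometricRecord("a", "male", 12.9, 160.0, 50.0)
        assert rec.age_group == 12
        assert rec.bmi == pytest.approx(19.53125)

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValidationError):
            AnthropometricRecord("a", "other", 12.0, 160.0, 50.0)


class TestStratify:
    def test_groups_by_sex_age_measure(self):
        recs = [
            AnthropometricRecord(str(i), sex, 12.0 + 0.09 * i, 150.0 + i, 40.0 + i)
            for i, sex in enumerate(["male"] * 5 + ["female"] * 5)
        ]
        groups = stratify(records_to_frame(recs))
        assert len(groups) == 6  # 2 sexes x 3 measures, age 12 only
        assert all(len(v) == 5 for v in groups.values())

    def test_floor_age_convention(self):
        frame = records_to_frame([AnthropometricRecord("a", "male", 12.9, 160, 50)])
        groups = stratify(frame)
        assert ("male", 12, "height") in groups

    def test_out_of_window_records_excluded(self):
        recs = [
            AnthropometricRecord("a", "male", 11.5, 150, 40),
            AnthropometricRecord("b", "male", 12.5, 150, 40),
            AnthropometricRecord("c", "male", 17.2, 150, 40),
        ]
        groups = stratify(records_to_frame(recs))
        assert len(groups[("male", 12, "height")]) == 1
        assert ("male", 11, "height") not in groups


class TestBuildReference:
    def test_injected_published_parameters_reproduce_cells(self, published_table):
        # bypass fitting: published boys' height triples straight to percentiles
        override = {
            ("male", row.age_group, "height"): row.params
            for row in published_table.rows
            if row.sex == "male" and row.measure == "height"
        }
        rng = np.random.default_rng(0)
        cohort = small_cohort(
            rng,
            {
                (s, a, m): LMSTriple(1.0, 50.0 if m != "height" else 150.0, 0.1)
                for s in ("male",)
                for a in range(12, 17)
                for m in ("height", "weight")
            },
            n=25,
            ages=range(12, 17),
        )
        table = build_reference(
            cohort, BuildOptions(sexes=("male",), params_override=override)
        )
        for row in published_table.rows:
            if row.sex != "male" or row.measure != "height":
                continue
            built = table.get_row("male", row.age_group, "height")
            for label, printed in row.percentiles.items():
                assert built.percentiles[label] == pytest.approx(printed, abs=0.011)

    def test_fitted_median_recovers_generating_mu(self, published_table):
        triples = {
            (r.sex, r.age_group, r.measure): r.params
            for r in published_table.rows
            if r.sex == "male" and r.measure in ("height", "weight")
        }
        rng = np.random.default_rng(77)
        cohort = small_cohort(rng, triples, n=1200, ages=range(12, 17))
        table = build_reference(cohort, BuildOptions(sexes=("male",)))
        for age in range(12, 17):
            true_mu = triples[("male", age, "height")].mu
            assert table.get_row("male", age, "height").params.mu == pytest.approx(
                true_mu, rel=0.01
            )

    def test_rows_self_consistent_and_p50_in_central_band(self, published_table):
        triples = {
            (r.sex, r.age_group, r.measure): r.params
            for r in published_table.rows
            if r.sex == "female" and r.measure in ("height", "weight")
        }
        rng = np.random.default_rng(3)
        cohort = small_cohort(rng, triples, n=300, sexes=("female",), ages=(12,))
        opts = BuildOptions(sexes=("female",), age_window=(12, 12))
        table = build_reference(cohort, opts)
        groups = stratify(cohort, (12, 12))
        for row in table.rows:
            for spec in table.percentile_sets[row.measure]:
                assert row.percentiles[spec.label] == centile(row.params, spec)
            values = groups[(row.sex, row.age_group, row.measure)]
            q40, q60 = np.quantile(values, [0.40, 0.60])
            assert q40 <= row.params.mu <= q60

    def test_build_is_reproducible(self, published_table):
        triples = {
            (r.sex, r.age_group, r.measure): r.params
            for r in published_table.rows
            if r.sex == "male" and r.measure in ("height", "weight")
        }
        cohorts = [
            small_cohort(np.random.default_rng(8), triples, n=120) for _ in range(2)
        ]
        opts = BuildOptions(sexes=("male",), age_window=(12, 12))
        frames = [build_reference(c, opts).to_frame() for c in cohorts]
        pd.testing.assert_frame_equal(frames[0], frames[1])

    def test_undersized_group_raises_unless_skipped(self, published_table):
        triples = {
            (r.sex, r.age_group, r.measure): r.params
            for r in published_table.rows
            if r.sex == "male" and r.measure in ("height", "weight")
        }
        cohort = small_cohort(np.random.default_rng(1), triples, n=10)
        opts = BuildOptions(sexes=("male",), age_window=(12, 12))
        with pytest.raises(ValidationError, match="below the minimum"):
            build_reference(cohort, opts)
        table = build_reference(
            cohort,
            BuildOptions(sexes=("male",), age_window=(12, 12), skip_unfittable=True),
        )
        assert table.rows == []


class TestSmoothSeries:
    def test_interpolation_limit_returns_series_unchanged(self, published_table):
        series = {
            r.age_group: r.params
            for r in published_table.rows
            if r.sex == "male" and r.measure == "height"
        }
        assert smooth_series(series, edf=len(series)) == series

    def test_constant_series_unchanged(self):
        series = {a: LMSTriple(1.0, 50.0, 0.1) for a in range(12, 17)}
        for edf in (1, 2, 3):
            out = smooth_series(series, edf)
            for age in series:
                assert out[age].mu == pytest.approx(50.0)
                assert out[age].lam == pytest.approx(1.0)

    def test_cubic_fit_of_monotone_medians_stays_monotone(self, published_table):
        series = {
            r.age_group: r.params
            for r in published_table.rows
            if r.sex == "male" and r.measure == "height"
        }
        out = smooth_series(series, edf=3)
        mus = [out[a].mu for a in sorted(out)]
        assert all(b >= a for a, b in zip(mus, mus[1:]))

    def test_excess_edf_rejected(self):
        series = {12: LMSTriple(1, 50, 0.1), 13: LMSTriple(1, 51, 0.1)}
        with pytest.raises(ValidationError):
            smooth_series(series, edf=3)


class TestMedianGrowthSummary:
    def test_published_growth_and_gain(self, published_table):
        summary = median_growth_summary(published_table).set_index(["sex", "measure"])
        assert summary.loc[("male", "height"), "median_growth"] == pytest.approx(18.07)
        assert summary.loc[("male", "weight"), "median_growth"] == pytest.approx(12.30)
        assert summary.loc[("female", "height"), "median_growth"] == pytest.approx(10.49)

    def test_single_age_flagged_with_zero_growth(self, published_table):
        from growthref.reference import PercentileTable

        rows = [r for r in published_table.rows if r.age_group == 12 and r.sex == "male"]
        table = PercentileTable(rows=rows, percentile_sets=published_table.percentile_sets)
        summary = median_growth_summary(table)
        assert (summary["median_growth"] == 0).all()
        assert summary["single_age"].all()
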
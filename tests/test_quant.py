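"""Tests of standard-curve quantification, rescaling and filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import singlebud as sb
from singlebud.quant import (DegenerateCurveError, InsufficientDilutionError,
                             ZeroMedianError)


class TestStandardCurve:
    def test_perfect_doubling_efficiency_one(self):
        pts = [(0, 30), (1, 26.6781), (2, 23.3562), (3, 20.0343)]
        curve = sb.fit_standard_curve(pts, gene="g")
        assert curve.slope == pytest.approx(-3.3219, abs=1e-4)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_lower_efficiency_from_steeper_slope(self):
        pts = [(q, 31.0 - 3.5 * q) for q in range(5)]
        curve = sb.fit_standard_curve(pts)
        assert curve.efficiency == pytest.approx(10 ** (1 / 3.5) - 1, abs=1e-6)

    def test_two_points_insufficient(self):
        with pytest.raises(InsufficientDilutionError):
            sb.fit_standard_curve([(0, 30), (1, 27)])

    def test_nonnegative_slope_degenerate(self):
        with pytest.raises(DegenerateCurveError):
            sb.fit_standard_curve([(0, 20), (1, 25), (2, 30)])

    def test_quantity_inversion_closed_forms(self):
        curve = sb.StandardCurve("g", slope=-3.3219, intercept=30.0,
                                 r_squared=1.0)
        assert sb.cq_to_quantity(30.0, curve) == pytest.approx(1.0)
        assert sb.cq_to_quantity(30.0 - 3.3219, curve) == pytest.approx(10.0)
        assert sb.cq_to_quantity(25.0, curve) == pytest.approx(32.0, rel=1e-3)

    def test_fit_then_invert_recovers_quantities(self):
        curve0 = sb.StandardCurve("g", slope=-3.45, intercept=33.0,
                                  r_squared=1.0)
        qty = np.array([1.0, 3.0, 10.0, 55.0, 400.0])
        cqs = curve0.intercept + curve0.slope * np.log10(qty)
        fit = sb.fit_standard_curve(list(zip(np.log10(qty), cqs)))
        back = [sb.cq_to_quantity(c, fit) for c in cqs]
        np.testing.assert_allclose(back, qty, rtol=1e-6)


class TestReplicatesAndRatios:
    def test_mean_and_spread_flag(self):
        assert sb.collapse_replicates([20.0, 20.2]) == (pytest.approx(20.1), False)
        mean, flagged = sb.collapse_replicates([20.0, 21.0])
        assert mean == pytest.approx(20.5) and flagged
        mean, flagged = sb.collapse_replicates([])
        assert np.isnan(mean) and not flagged

    def test_relative_expression_cases(self):
        assert sb.relative_expression(5.0, 5.0) == 1.0
        assert sb.relative_expression(10.0, 2.0) == 5.0
        assert np.isnan(sb.relative_expression(3.0, 0.0))


def _stage_table(medians: dict[str, float], n_per_stage: int = 4):
    rows, idx, stages = [], [], []
    for stage, med in medians.items():
        for i in range(n_per_stage):
            rows.append(med * (0.8 + 0.1 * i) if med else 0.0)
            idx.append(f"{stage}_b{i}")
            stages.append(stage)
    values = pd.DataFrame({"g": rows}, index=idx)
    return sb.ExpressionTable(values, pd.Series(stages, index=idx))


class TestRescale:
    def test_divides_by_highest_stage_median(self):
        table = _stage_table({"S1": 4.0, "S2": 2.0, "S3": 1.0, "S4": 0.5})
        top = table.stage_medians("g").max()
        out = sb.rescale_to_max_stage_median(table)
        assert out.rescaled
        meds = out.stage_medians("g")
        assert meds.max() == pytest.approx(1.0)
        np.testing.assert_allclose(
            out.values["g"], table.values["g"] / top)

    def test_idempotent(self):
        table = _stage_table({"S1": 4.0, "S2": 2.0})
        once = sb.rescale_to_max_stage_median(table)
        twice = sb.rescale_to_max_stage_median(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    @given(c=st.floats(1e-3, 1e3, allow_nan=False))
    def test_scale_invariant(self, c):
        table = _stage_table({"S1": 3.0, "S2": 1.5, "S3": 0.75})
        scaled_in = table.with_values(table.values * c)
        a = sb.rescale_to_max_stage_median(table)
        b = sb.rescale_to_max_stage_median(scaled_in)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)

    def test_all_zero_gene_errors(self):
        table = _stage_table({"S1": 0.0, "S2": 0.0})
        with pytest.raises(ZeroMedianError, match="g"):
            sb.rescale_to_max_stage_median(table)


class TestDetectionFilter:
    def _table(self, detected_frac: float):
        n = 20
        vals = pd.DataFrame({
            "ok": np.linspace(1, 2, n),
            "weak": [1.0 if i < detected_frac * n else np.nan
                     for i in range(n)],
        }, index=[f"b{i}" for i in range(n)])
        stages = pd.Series(["S1"] * n, index=vals.index)
        return sb.ExpressionTable(vals, stages)

    def test_fully_missing_gene_dropped(self):
        out, dropped = sb.filter_undetected_genes(self._table(0.0), 0.5)
        assert dropped == ["weak"] and out.genes == ["ok"]

    def test_complete_table_unchanged(self):
        table = self._table(1.0)
        out, dropped = sb.filter_undetected_genes(table, 0.5)
        assert dropped == [] and out.genes == table.genes

    def test_forty_percent_detection_below_half_threshold(self):
        out, dropped = sb.filter_undetected_genes(self._table(0.4), 0.5)
        assert dropped == ["weak"]

    def test_all_dropped_errors(self):
        table = self._table(0.0).subset(genes=["weak"])
        with pytest.raises(ValueError):
            sb.filter_undetected_genes(table, 0.5)


class TestRoundTrip:
    def test_noise_free_cq_recovers_expression(self):
        design = sb.study_design(seed=21, outlier_rate=0.0,
                                 stage_sizes={"S1": 4, "S2": 4, "S3": 8, "S4": 4})
        records, dilutions, _, truth = sb.generate_cq(design, cq_noise_sd=0.0)
        series: dict[str, list] = {}
        for row in dilutions.itertuples(index=False):
            series.setdefault(row.gene, []).append((row.log10_quantity, row.cq))
        curves = {g: sb.fit_standard_curve(pts, g) for g, pts in series.items()}
        table, qc = sb.quantify_cq_table(records, curves,
                                         reference_gene="SAND-like")
        detectable = [g.name for g in design.genes if g.detectable]
        got = table.values[detectable]
        want = truth.values[detectable].loc[got.index]
        np.testing.assert_allclose(got, want, rtol=1e-2)
        assert not qc["high_spread"].any()

    def test_replicate_noise_rarely_flags_spread(self):
        design = sb.study_design(seed=22, stage_sizes={"S1": 5, "S2": 5,
                                                       "S3": 20, "S4": 5})
        records, _, curves, _ = sb.generate_cq(design, cq_noise_sd=0.1)
        table, qc = sb.quantify_cq_table(records, curves,
                                         reference_gene="SAND-like")
        assert qc["high_spread"].mean() < 0.05

    def test_undetectable_gene_emitted_missing(self):
        design = sb.study_design(seed=23, stage_sizes={"S1": 3, "S2": 3,
                                                       "S3": 5, "S4": 3})
        records, _, curves, _ = sb.generate_cq(design)
        table, _ = sb.quantify_cq_table(records, curves,
                                        reference_gene="SAND-like")
        assert table.values["DAM2-like"].isna().all()
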
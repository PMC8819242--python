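"""Rate ratios, frequency weighting and the observed-vs-predicted report."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from t2risk import (
    ReconciliationError,
    RiskScale,
    TrialTable,
    UndefinedRatioError,
    build_comparison,
    diff_against_printed,
    frequency_weighted_mean,
    load_table1_fixture,
    predicted_table_from_scale,
    rate_ratio,
    render_report,
    reproduce_table1,
    weighted_summary_from_printed,
)
from t2risk.compare import format_percent, format_ratio, round_half_away
from t2risk.trial_ingest import StratumArmRecord
from t2risk.risk_model import STRATA, Type2Stratum


class TestRateRatio:
    def test_examples(self):
        assert rate_ratio(0.40, 0.26) == pytest.approx(0.65)  # reduction 35%
        assert rate_ratio(0.7, 0.7) == 1.0
        rr = rate_ratio(0.56, 0.58)
        assert rr == pytest.approx(1.0357, abs=1e-4)
        assert format_percent(1 - rr) == "-4%"

    def test_zero_control_is_undefined_not_inf(self):
        with pytest.raises(UndefinedRatioError):
            rate_ratio(0.0, 0.3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rate_ratio(-1, 0.3)


class TestFrequencyWeightedMean:
    def test_printed_low_stratum_summary(self):
        # printed per-trial observed reductions with stratum-n weights
        got = frequency_weighted_mean([0.41, 0.20, -0.04, 0.14], [78, 405, 245, 86])
        assert got == pytest.approx(0.141548, abs=1e-6)
        assert format_percent(got) == "14%"

    def test_printed_very_high_summary(self):
        got = frequency_weighted_mean([0.81, 0.60], [105, 138])
        assert got == pytest.approx(0.690741, abs=1e-6)
        assert format_percent(got) == "69%"

    def test_single_value_and_na_exclusion(self):
        assert frequency_weighted_mean([0.3], [17]) == 0.3
        assert frequency_weighted_mean([0.5, np.nan], [10, 99]) == 0.5
        with pytest.raises(ValueError, match="empty"):
            frequency_weighted_mean([np.nan], [10])
        with pytest.raises(ValueError):
            frequency_weighted_mean([0.1, 0.2], [1, 0])

    values = st.lists(st.floats(-1, 1), min_size=1, max_size=8)

    @given(st.data())
    def test_linearity_and_hull(self, data):
        v = data.draw(self.values)
        w = data.draw(
            st.lists(st.floats(0.1, 100), min_size=len(v), max_size=len(v))
        )
        m = frequency_weighted_mean(v, w)
        # 1 - mean(rr) == mean(1 - rr) under identical weights
        assert 1 - m == pytest.approx(frequency_weighted_mean([1 - x for x in v], w), abs=1e-9)
        # convex hull bound
        assert min(v) - 1e-12 <= m <= max(v) + 1e-12
        # invariance to positive rescaling of all weights
        assert m == pytest.approx(
            frequency_weighted_mean(v, [3.7 * x for x in w]), abs=1e-9
        )


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.6168, "62%"), (-0.0357, "-4%"), (0.0, "0%"), (0.125, "13%"), (-0.125, "-13%")],
    )
    def test_percent_half_away_from_zero(self, x, expected):
        assert format_percent(x) == expected

    def test_ratio_two_decimals(self):
        assert format_ratio(0.5775) == "0.58"
        assert format_ratio(1.0357) == "1.04"
        assert round_half_away(-2.5) == -3.0


def _table(cells, source="observed"):
    records = [
        StratumArmRecord(t, Type2Stratum(s), a, n, r, source=source)
        for (t, s, a, n, r) in cells
    ]
    return TrialTable.from_records(records)


class TestBuildComparison:
    def test_fixture_summaries_and_exclusions(self, fixture_table):
        report = build_comparison(fixture_table, predicted=fixture_table)
        by = report.summaries.set_index("stratum")
        assert by.loc["low", "total_n"] == 814
        assert by.loc["high", "total_n"] == 3925
        # very-high restricted to Novel START and CAPTAIN
        assert by.loc["very_high", "total_n"] == 243
        vh_rows = report.rows[report.rows.stratum == "very_high"]
        assert sorted(vh_rows.trial_id) == ["CAPTAIN", "NovelSTART"]
        assert ("QUEST", "very_high") in report.excluded
        assert ("DREAM", "very_high") in report.excluded
        # predicted rate ratios recomputed from the printed predicted cells
        assert by.loc["high", "predicted_mean_rr"] == pytest.approx(0.58, abs=0.011)
        assert by.loc["low", "predicted_mean_rr"] == 1.0

    def test_generated_predictions_are_trial_invariant(self, fixture_table):
        report = build_comparison(fixture_table)  # predictions from the scale
        high = report.rows[report.rows.stratum == "high"]
        assert np.allclose(high.predicted_rr, 0.58)
        assert report.summaries.set_index("stratum").loc[
            "high", "predicted_mean_rr"
        ] == pytest.approx(0.58)

    def test_identical_tables_give_zero_differences(self):
        cells = [
            ("T1", "low", "control", 10, 0.5),
            ("T1", "low", "active", 10, 0.4),
            ("T1", "high", "control", 20, 1.0),
            ("T1", "high", "active", 20, 0.6),
        ]
        obs = _table(cells)
        pred = _table(cells, source="predicted")
        report = build_comparison(obs, predicted=pred)
        assert np.allclose(report.rows.observed_rr, report.rows.predicted_rr)
        s = report.summaries
        assert np.allclose(s.observed_mean_rr, s.predicted_mean_rr)

    def test_missing_predicted_key_is_reconciliation_error(self):
        obs = _table(
            [
                ("T1", "low", "control", 10, 0.5),
                ("T1", "low", "active", 10, 0.4),
                ("T1", "high", "control", 20, 1.0),
                ("T1", "high", "active", 20, 0.6),
            ]
        )
        pred = _table(
            [("T1", "low", "control", None, 0.5), ("T1", "low", "active", None, 0.5)],
            source="predicted",
        )
        with pytest.raises(ReconciliationError, match=r"\(T1, high"):
            build_comparison(obs, predicted=pred)

    def test_missing_low_rate_blocks_generated_predictions(self):
        obs = _table(
            [("T1", "high", "control", 20, 1.0), ("T1", "high", "active", 20, 0.6)]
        )
        with pytest.raises(ReconciliationError, match="biomarker-low"):
            build_comparison(obs)


class TestPrintedModeSummaries:
    def test_reproduces_printed_weighted_cells(self):
        s = weighted_summary_from_printed().set_index(["stratum", "source"])
        assert round_half_away(s.loc[("low", "observed"), "mean_rr"], 2) == 0.86
        assert format_percent(s.loc[("low", "observed"), "mean_reduction"]) == "14%"
        assert format_percent(s.loc[("very_high", "observed"), "mean_reduction"]) == "69%"
        assert format_percent(s.loc[("very_high", "predicted"), "mean_reduction"]) == "72%"
        assert s.loc[("high", "predicted"), "mean_rr"] == pytest.approx(0.58)
        assert s.loc[("low", "predicted"), "mean_reduction"] == 0.0
        assert s.loc[("very_high", "observed"), "total_n"] == 243


class TestDiffBlock:
    def test_flags_known_irreproducible_cells(self):
        locations = {d.location for d in diff_against_printed()}
        # the published high-stratum observed weighted rr (0.59) is not
        # recoverable from the printed per-trial cells
        assert "weighted_mean/high/observed rate ratio" in locations
        assert "weighted_mean/high/observed reduction" in locations
        # Novel START reductions were printed from unrounded internal rates
        for s in ("low", "high", "very_high"):
            assert f"NovelSTART/{s}/observed reduction" in locations
        # the very-high predicted active cells contradict the counterfactual rule
        assert "QUEST/very_high/predicted active rate" in locations
        assert "DREAM/very_high/predicted active rate" in locations

    def test_reproducible_cells_not_flagged(self):
        locations = {d.location for d in diff_against_printed()}
        for loc in (
            "CAPTAIN/high/observed reduction",
            "QUEST/high/observed reduction",
            "QUEST/low/observed reduction",
            "DREAM/high/observed reduction",
            "DREAM/low/observed reduction",
            "CAPTAIN/very_high/observed reduction",
            "weighted_mean/low/observed reduction",
            "weighted_mean/low/observed rate ratio",
            "weighted_mean/very_high/observed reduction",
            "weighted_mean/high/predicted reduction",
            "weighted_mean/high/predicted rate ratio",
        ):
            assert loc not in locations, loc

    def test_observed_reductions_within_five_points(self, fixture_table, printed_reductions):
        """Recomputed observed per-trial reductions stay within +/-5pp of print."""
        per_trial = printed_reductions[
            (printed_reductions.trial_id != "weighted_mean")
            & (printed_reductions.source == "observed")
        ]
        for row in per_trial.itertuples(index=False):
            c = fixture_table.rate(row.trial_id, row.stratum, "control")
            a = fixture_table.rate(row.trial_id, row.stratum, "active")
            recomputed = (1 - a / c) * 100
            assert abs(recomputed - row.reduction_pct) <= 5.0, row


class TestRender:
    def test_text_report_conventions(self):
        result = reproduce_table1()
        text = render_report(result.report, diffs=result.diffs)
        assert "62%" in text  # QUEST high observed reduction
        assert "-4%" in text  # QUEST low observed reduction
        assert "rr 0.58" in text  # high-stratum predicted weighted rr
        assert "excluded (missing observed arms): QUEST/very_high, DREAM/very_high" in text
        assert "not reproducible" in text
        assert "DREAM/very_high/predicted active rate" in text

    def test_json_and_csv_outputs(self, tmp_path):
        report = build_comparison(load_table1_fixture())
        d = report.to_json_dict()
        assert {"rows", "summaries", "excluded", "scale"} <= set(d)
        report.write_csv(tmp_path / "rows.csv")
        report.write_json(tmp_path / "report.json")
        assert (tmp_path / "rows.csv").exists() and (tmp_path / "report.json").exists()


def test_predicted_table_from_scale_shape():
    table = predicted_table_from_scale({"T1": 0.5}, RiskScale())
    assert len(table) == 6
    assert table.rate("T1", Type2Stratum.HIGH, "control", "predicted") == pytest.approx(0.5 / 0.58)
    assert table.rate("T1", Type2Stratum.VERY_HIGH, "active", "predicted") == 0.5
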
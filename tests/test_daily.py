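"""Daily aggregation, the 6-hour gap rule and sigma_d propagation."""

import numpy as np
import pandas as pd
import pytest

from aqfusion.daily import (
    AggregationSpec,
    aggregate_daily,
    daily_mode,
    gap_rule_mask,
    propagate_uncertainty,
)
from aqfusion.gapfill import ImputedSeries, RegularSeries, SSMParams


def _imputed(values, missing_idx, variances=None, step="1h",
             start="2016-06-01"):
    """Build an ImputedSeries directly: observed values with the given
    entries flagged missing and filled with the same numbers."""
    values = np.asarray(values, dtype=float)
    base_values = values.copy()
    base_values[list(missing_idx)] = np.nan
    base = RegularSeries(start=pd.Timestamp(start), step=step, values=base_values)
    var = np.zeros(len(values))
    if variances is not None:
        for i, v in variances.items():
            var[i] = v
    return ImputedSeries(
        base=base,
        filled_values=values,
        imputed_mask=np.isnan(base_values),
        smoothed_variance=var,
        params=SSMParams(A=0.9, B=1.0),
    )


class TestAggregate:
    def test_mean_of_full_day(self):
        series = RegularSeries(start="2016-06-01", step="1h",
                               values=np.arange(1.0, 25.0))
        out = aggregate_daily(series, AggregationSpec("mean"))
        assert len(out) == 1
        assert out.values[0] == pytest.approx(12.5)
        assert out.sigma_d[0] == 0.0

    @pytest.mark.parametrize("func,expected", [
        ("mean", 12.5), ("max", 24.0), ("min", 1.0), ("sum", 300.0),
    ])
    def test_numeric_functions_match_brute_force(self, func, expected):
        series = RegularSeries(start="2016-06-01", step="1h",
                               values=np.arange(1.0, 25.0))
        out = aggregate_daily(series, AggregationSpec(func))
        assert out.values[0] == pytest.approx(expected)

    def test_unknown_function_rejected(self):
        with pytest.raises(ValueError, match="unknown aggregation"):
            AggregationSpec("median")

    def test_seven_hour_gap_invalidates_day(self):
        imp = _imputed(np.full(48, 10.0), missing_idx=range(8, 15))  # 7 h run
        out = aggregate_daily(imp, AggregationSpec("mean"))
        assert np.isnan(out.values[0])
        assert np.isnan(out.sigma_d[0])  # missing day has missing sigma_d
        assert not np.isnan(out.values[1])

    def test_six_hour_gap_keeps_day(self):
        imp = _imputed(np.full(48, 10.0), missing_idx=range(8, 14))  # 6 h run
        out = aggregate_daily(imp, AggregationSpec("mean"))
        assert out.values[0] == pytest.approx(10.0)

    def test_bihourly_spacing_is_not_a_gap(self):
        series = RegularSeries(start="2016-06-01", step="2h",
                               values=np.linspace(5, 10, 12))
        out = aggregate_daily(series, AggregationSpec("mean"))
        assert not np.isnan(out.values[0])

    def test_bihourly_four_entry_run_invalidates(self):
        # 4 consecutive missing bi-hourly entries span 8 h > 6 h
        imp = _imputed(np.full(12, 3.0), missing_idx=range(2, 6), step="2h")
        out = aggregate_daily(imp, AggregationSpec("mean"))
        assert np.isnan(out.values[0])

    def test_bihourly_three_entry_run_kept(self):
        imp = _imputed(np.full(12, 3.0), missing_idx=range(2, 5), step="2h")
        out = aggregate_daily(imp, AggregationSpec("mean"))
        assert out.values[0] == pytest.approx(3.0)

    def test_gap_crossing_midnight_hits_both_days(self):
        imp = _imputed(np.full(48, 1.0), missing_idx=range(20, 28))
        out = aggregate_daily(imp, AggregationSpec("mean"))
        assert np.isnan(out.values[0]) and np.isnan(out.values[1])

    def test_gap_rule_monotone(self):
        """Extending a consecutive missing run never revalidates a day."""
        base_missing = list(range(8, 15))
        imp = _imputed(np.full(24, 2.0), missing_idx=base_missing)
        assert gap_rule_mask(imp).iloc[0]
        for extra in (15, 16, 17):
            base_missing.append(extra)
            imp = _imputed(np.full(24, 2.0), missing_idx=base_missing)
            assert gap_rule_mask(imp).iloc[0]

    def test_partial_edge_day_aggregated(self):
        series = RegularSeries(start="2016-06-01 20:00", step="1h",
                               values=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]))
        out = aggregate_daily(series, AggregationSpec("mean"))
        assert len(out) == 2
        assert out.values[0] == pytest.approx(2.5)  # hours 20-23
        assert out.values[1] == pytest.approx(5.5)  # hours 0-1 next day


class TestDailyMode:
    def test_most_frequent(self):
        assert daily_mode(["N", "N", "E"]) == "N"

    def test_tie_breaks_to_earliest(self):
        assert daily_mode(["N", "E"]) == "N"
        assert daily_mode(["E", "N"]) == "E"

    def test_two_category_exhaustive(self):
        """Every 2-category sequence of length <= 4: winner is the majority,
        or the earliest on ties (checked against brute-force enumeration)."""
        from itertools import product
        for n in (1, 2, 3, 4):
            for seq in product("AB", repeat=n):
                na, nb = seq.count("A"), seq.count("B")
                if na > nb:
                    expected = "A"
                elif nb > na:
                    expected = "B"
                else:
                    expected = seq[0]
                assert daily_mode(seq) == expected

    def test_constant(self):
        assert daily_mode(["S"] * 12) == "S"

    def test_empty_day_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            daily_mode([])

    def test_mode_aggregation_of_categorical_day(self):
        values = np.full(24, 1.0)
        series = RegularSeries(start="2016-06-01", step="1h", values=values)
        out = aggregate_daily(series, AggregationSpec("mode"))
        assert out.values[0] == 1.0


class TestSigmaD:
    def test_fully_observed_day_zero(self):
        imp = _imputed(np.full(24, 9.0), missing_idx=[])
        sigma = propagate_uncertainty(imp)
        assert sigma.iloc[0] == 0.0

    def test_single_imputed_hour(self):
        imp = _imputed(np.full(24, 9.0), missing_idx=[10], variances={10: 4.0})
        sigma = propagate_uncertainty(imp)
        assert sigma.iloc[0] == pytest.approx(np.sqrt(4.0) / 24.0)

    def test_all_entries_imputed(self):
        v = 2.5
        imp = _imputed(np.full(24, 9.0), missing_idx=range(24),
                       variances={i: v for i in range(24)})
        # bypass the gap rule to check the formula itself
        var = np.where(imp.imputed_mask, imp.smoothed_variance, 0.0)
        sigma = np.sqrt(var.sum()) / 24.0
        assert sigma == pytest.approx(np.sqrt(24 * v) / 24.0)

    def test_bihourly_divisor_is_twelve(self):
        imp = _imputed(np.full(12, 9.0), missing_idx=[4], variances={4: 9.0},
                       step="2h")
        sigma = propagate_uncertainty(imp)
        assert sigma.iloc[0] == pytest.approx(3.0 / 12.0)

    def test_observed_entries_do_not_contribute(self):
        imp = _imputed(np.full(24, 9.0), missing_idx=[3], variances={3: 1.0})
        # give observed entries nonzero smoothed variance, as the smoother does
        imp.smoothed_variance[:] = 0.5
        imp.smoothed_variance[3] = 1.0
        sigma = propagate_uncertainty(imp)
        assert sigma.iloc[0] == pytest.approx(1.0 / 24.0)

    def test_monte_carlo_agreement(self):
        """sigma_d matches the SD of daily means with missing entries
        resampled from their smoothed Gaussians, within 3 MC SEs."""
        rng = np.random.default_rng(0)
        variances = {5: 1.2, 6: 2.0, 14: 0.7}
        values = 10.0 + rng.normal(0, 2, 24)
        imp = _imputed(values, missing_idx=list(variances), variances=variances)
        sigma = propagate_uncertainty(imp).iloc[0]

        n_mc = 4000
        draws = np.empty(n_mc)
        for k in range(n_mc):
            sample = imp.filled_values.copy()
            for i, v in variances.items():
                sample[i] += rng.normal(0, np.sqrt(v))
            draws[k] = sample.mean()
        mc_sd = draws.std(ddof=1)
        se = mc_sd / np.sqrt(2 * (n_mc - 1))  # SE of an SD estimate
        assert abs(mc_sd - sigma) < 3 * se
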
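"""Oxygen time-series assembly, consumption metrics, and group comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

import spheroxi as sx
from spheroxi.chambers import Chamber, ChamberMap
from spheroxi.consumption import (
    OxygenSeries,
    assemble_series,
    compare_groups,
    compute_metrics,
    molar_rate,
)

TIMEPOINTS = np.arange(13) * 5.0


def _map(occupancies):
    chambers = [
        Chamber(chamber_id=i + 1, center=(20.0, 20.0 + 50 * i), radius=10.0, occupancy=occ)
        for i, occ in enumerate(occupancies)
    ]
    return ChamberMap(chambers=chambers, image_shape=(40, 40 + 50 * len(occupancies)), pixel_size=2.0)


def _table(chamber_ids, timepoints=TIMEPOINTS, o2=19.0):
    rows = [
        {"chamber_id": cid, "timepoint_min": t, "mean_o2_pct": o2}
        for cid in chamber_ids
        for t in timepoints
    ]
    return pd.DataFrame(rows)


def untreated_curve(t):
    """Mono-exponential 19.2 -> 13.8 hitting 13.9 at 25 min."""
    rate = math.log((19.2 - 13.8) / 0.1) / 25.0
    return 13.8 + (19.2 - 13.8) * np.exp(-rate * np.asarray(t, float))


class TestAssembleSeries:
    def test_hour_long_series_spans_zero_to_sixty(self):
        cmap = _map(["empty", "spheroid"])
        series = assemble_series(_table([1, 2]), cmap)
        assert len(series) == 1  # empty chambers are references, not samples
        assert series[0].timepoints[0] == 0.0
        assert series[0].timepoints[-1] == 60.0
        assert not series[0].incomplete

    def test_only_empty_chambers_yields_no_series(self):
        cmap = _map(["empty", "empty"])
        assert assemble_series(_table([1, 2]), cmap) == []

    def test_missing_timepoint_flagged_incomplete(self):
        cmap = _map(["spheroid", "spheroid"])
        full = _table([1], TIMEPOINTS)
        partial = _table([2], TIMEPOINTS[:-1])
        series = assemble_series(pd.concat([full, partial]), cmap)
        flags = {s.chamber_id: s.incomplete for s in series}
        assert flags == {1: False, 2: True}
        assert len([s for s in series if s.chamber_id == 2][0].o2) == 12

    def test_unknown_chamber_id_rejected(self):
        with pytest.raises(KeyError):
            assemble_series(_table([9]), _map(["spheroid"]))


class TestComputeMetrics:
    def test_constant_series_has_no_consumption(self):
        s = OxygenSeries(1, TIMEPOINTS, np.full(13, 20.9))
        m = compute_metrics(s)
        assert m.initial_rate == pytest.approx(0.0, abs=1e-12)
        assert m.total_drop == pytest.approx(0.0, abs=1e-12)
        assert m.plateau_o2 == pytest.approx(20.9)

    def test_untreated_curve_plateau_and_settling_time(self):
        """The printed untreated shape plateaus near 13.8 within 30 min."""
        s = OxygenSeries(1, TIMEPOINTS, untreated_curve(TIMEPOINTS))
        m = compute_metrics(s)
        assert m.plateau_o2 == pytest.approx(13.8, abs=0.05)
        assert m.time_to_plateau <= 30.0
        assert not m.censored
        assert m.total_drop == pytest.approx(19.2 - m.plateau_o2, abs=1e-9)

    def test_linear_ramp_slope(self):
        o2 = 20.0 - 0.2 * TIMEPOINTS
        m = compute_metrics(OxygenSeries(1, TIMEPOINTS, o2))
        assert m.initial_rate == pytest.approx(0.2, abs=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            compute_metrics(OxygenSeries(1, TIMEPOINTS[:6], np.full(6, 19.0)))

    def test_time_origin_shift_invariance(self):
        """Adding a constant to the clock leaves every metric unchanged."""
        o2 = untreated_curve(TIMEPOINTS)
        m0 = compute_metrics(OxygenSeries(1, TIMEPOINTS, o2))
        m1 = compute_metrics(OxygenSeries(1, TIMEPOINTS + 100.0, o2))
        assert m1.initial_rate == pytest.approx(m0.initial_rate)
        assert m1.plateau_o2 == pytest.approx(m0.plateau_o2)
        assert m1.total_drop == pytest.approx(m0.total_drop)
        assert m1.time_to_plateau == pytest.approx(m0.time_to_plateau + 100.0)


class TestMolarRate:
    def test_unit_conversion_oracle(self):
        """0.209 %/min in 9.4 nL at 200 uM solubility is 1.88e-14 mol/min."""
        m = sx.ConsumptionMetrics(1, 0.209, 13.8, 15.0, 5.4, False)
        assert molar_rate(m, 9.4, 200.0) == pytest.approx(1.88e-14, rel=1e-3)

    def test_zero_rate_and_volume_linearity(self):
        zero = sx.ConsumptionMetrics(1, 0.0, 19.0, 0.0, 0.0, False)
        assert molar_rate(zero, 9.4) == 0.0
        m = sx.ConsumptionMetrics(1, 0.1, 15.0, 20.0, 4.0, False)
        assert molar_rate(m, 18.8) == pytest.approx(2 * molar_rate(m, 9.4), rel=1e-12)

    def test_nonpositive_solubility_rejected(self):
        m = sx.ConsumptionMetrics(1, 0.1, 15.0, 20.0, 4.0, False)
        with pytest.raises(ValueError):
            molar_rate(m, 9.4, 0.0)


def _group(values_by_series):
    return [
        OxygenSeries(i + 1, TIMEPOINTS, np.asarray(v)) for i, v in enumerate(values_by_series)
    ]


class TestCompareGroups:
    def test_identical_groups_show_no_difference(self):
        values = [untreated_curve(TIMEPOINTS) + d for d in (-0.2, 0.0, 0.2)]
        table = compare_groups(_group(values), _group(values))
        np.testing.assert_allclose(table["t_statistic"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["p_value"], 1.0, atol=1e-12)
        assert not table["significant"].any()

    def test_swapping_groups_negates_t_and_preserves_p(self):
        rng = np.random.default_rng(0)
        a = [untreated_curve(TIMEPOINTS) + rng.normal(0, 0.3, 13) for _ in range(4)]
        b = [untreated_curve(TIMEPOINTS) + 1.0 + rng.normal(0, 0.3, 13) for _ in range(4)]
        ab = compare_groups(_group(a), _group(b))
        ba = compare_groups(_group(b), _group(a))
        np.testing.assert_allclose(ba["t_statistic"], -ab["t_statistic"], rtol=1e-12)
        np.testing.assert_allclose(ba["p_value"], ab["p_value"], rtol=1e-12)

    def test_power_at_two_percent_separation(self):
        """2% O2 mean separation at SD 0.5, n=10: significant in >= 95% of replicates."""
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 40
        t = np.array([0.0, 5.0])
        for _ in range(n_rep):
            a = [OxygenSeries(i, t, rng.normal(16.0, 0.5, 2)) for i in range(10)]
            b = [OxygenSeries(i, t, rng.normal(18.0, 0.5, 2)) for i in range(10)]
            table = compare_groups(a, b)
            hits += bool(table["significant"].all())
        assert hits / n_rep >= 0.95

    def test_untreated_vs_oligomycin_significance_pattern(self):
        """Divergent at 20 min while consumption is suppressed; converged by 60 min."""
        rng = np.random.default_rng(3)
        untreated = sx.untreated_kinetics()
        oligo = sx.oligomycin_kinetics()
        a = _group([
            [untreated.chamber_o2(t) for t in TIMEPOINTS] + rng.normal(0, 0.4, 13)
            for _ in range(6)
        ])
        b = _group([
            [oligo.chamber_o2(t) for t in TIMEPOINTS] + rng.normal(0, 0.4, 13)
            for _ in range(6)
        ])
        table = compare_groups(a, b).set_index("timepoint_min")
        assert bool(table.loc[20.0, "significant"])
        assert not bool(table.loc[60.0, "significant"])

    def test_small_group_rejected(self):
        g = _group([untreated_curve(TIMEPOINTS)])
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups(g, g)

    def test_bonferroni_only_tightens(self):
        rng = np.random.default_rng(9)
        a = _group([rng.normal(16.0, 0.5, 13) for _ in range(5)])
        b = _group([rng.normal(16.4, 0.5, 13) for _ in range(5)])
        plain = compare_groups(a, b)
        adj = compare_groups(a, b, bonferroni=True)
        assert adj["significant"].sum() <= plain["significant"].sum()
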
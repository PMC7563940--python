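"""Scenario period calculators: frozen worked values, identities, oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from compas_bc import (
    DomainError,
    GrowthRate,
    ModelConstants,
    ScenarioInputs,
    diameter_from_doublings,
    earliest_periods,
    earliest_scenario,
    grow,
    latest_periods,
    latest_scenario,
    round_half_up,
    seeded_at_surgery_window,
    seeding_spread_width_years,
    whole_history_identity,
)

D_PT = 15.1


class TestWorkedRapidBand:
    """The d_PT = 15.1 mm triple-negative worked case (TVDT band 10-135 d)."""

    def test_latest_scenario_periods(self):
        p = latest_periods(D_PT, 135)
        assert round_half_up(p.mts1_years, 2) == 4.34
        assert round_half_up(p.mts2_years, 2) == 6.56
        assert round_half_up(p.visible_years, 2) == 3.90
        assert round_half_up(p.survival_years, 2) == 10.47

    def test_earliest_scenario_periods(self):
        p = earliest_periods(10)
        assert round_half_up(p.mts1_years, 2) == 0.55
        assert round_half_up(p.mts2_years, 2) == 0.26
        assert round_half_up(p.visible_years, 2) == 0.29
        assert round_half_up(p.survival_years, 2) == 0.55

    def test_scenarios_from_band_inputs(self, registry):
        inputs = ScenarioInputs(D_PT, registry["V"])
        assert latest_scenario(inputs).tvdt_mts_days == 135
        assert earliest_scenario(inputs).tvdt_mts_days == 10
        assert latest_scenario(inputs).mts2_years == latest_periods(D_PT, 135).mts2_years


class TestSlowerBands:
    def test_intermediate_band_upper_cells(self):
        p = latest_periods(D_PT, 165)
        assert round_half_up(p.mts2_years, 2) == 8.02
        assert round_half_up(p.survival_years, 2) == 12.79

    def test_slowest_band_pre_surgery_latency(self):
        assert round_half_up(latest_periods(D_PT, 270).mts1_years, 2) == 8.69

    def test_band_minimum_gives_window_low_end(self):
        assert round_half_up(latest_periods(D_PT, 136).mts2_years, 2) == 6.61

    def test_earliest_scenario_at_intermediate_band(self):
        # not a printed cell: the earliest scenario applied at TVDT 136 d
        p = earliest_periods(136)
        assert round_half_up(p.mts2_years, 2) == 3.54


class TestSeededAtSurgeryWindow:
    def test_rapid_plus_window(self):
        lo, hi = seeded_at_surgery_window(D_PT, 135)
        assert round_half_up(lo, 2) == 6.56
        assert hi == pytest.approx(29.441343 * 135 / 365.25, abs=1e-4)
        width = seeding_spread_width_years(D_PT, 135)
        assert round_half_up(width, 2) == 4.34

    @pytest.mark.parametrize(
        "tvdt, expected_width", [(165, 5.31), (195, 6.27), (230, 7.40)]
    )
    def test_plus_window_widths_match_published_periods(self, tvdt, expected_width):
        assert round_half_up(seeding_spread_width_years(D_PT, tvdt), 2) == expected_width

    def test_window_low_is_the_latest_scenario_latency(self):
        lo, _ = seeded_at_surgery_window(D_PT, 230)
        assert lo == latest_periods(D_PT, 230).mts2_years


class TestInvariants:
    @given(d_pt=st.floats(min_value=1.2, max_value=60.0))
    @settings(derandomize=True, max_examples=100)
    def test_whole_history_is_sixty_doublings(self, d_pt):
        """The PT terms cancel: every diameter yields exactly 60 doublings."""
        assert whole_history_identity(d_pt) == pytest.approx(60.0, abs=1e-9)

    @given(
        d_pt=st.floats(min_value=2.0, max_value=60.0),
        t1=st.floats(min_value=10, max_value=270),
        t2=st.floats(min_value=10, max_value=270),
    )
    @settings(derandomize=True, max_examples=100)
    def test_periods_increase_with_tvdt(self, d_pt, t1, t2):
        if t1 == t2:
            return
        lo, hi = sorted((t1, t2))
        a, b = latest_periods(d_pt, lo), latest_periods(d_pt, hi)
        assert a.mts1_years < b.mts1_years
        assert a.mts2_years < b.mts2_years
        assert a.visible_years < b.visible_years

    @given(
        d1=st.floats(min_value=2.0, max_value=60.0),
        d2=st.floats(min_value=2.0, max_value=60.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_larger_pt_means_longer_mts1_and_shorter_mts2(self, d1, d2):
        if abs(d1 - d2) < 1e-6:
            return
        small, large = sorted((d1, d2))
        a, b = latest_periods(small, 135), latest_periods(large, 135)
        assert a.mts1_years < b.mts1_years
        assert a.mts2_years > b.mts2_years

    def test_survival_is_exactly_mts2_plus_visible(self):
        for p in (latest_periods(D_PT, 200), earliest_periods(77)):
            assert p.survival_years == p.mts2_years + p.visible_years

    def test_pt_below_seeding_size_rejected(self):
        with pytest.raises(DomainError):
            latest_periods(1.01, 135)  # < 20 doublings

    def test_scenario_inputs_require_seeded_pt(self, registry):
        with pytest.raises(DomainError):
            ScenarioInputs(0.9, registry["V"])


def _day_stepped_crossing(d0: float, threshold: float, tvdt: float) -> int:
    """Brute-force oracle: first whole day the diameter reaches threshold."""
    rate = GrowthRate(tvdt)
    days = np.arange(0, int(60 * tvdt) + 2)
    diam = d0 * 2.0 ** (days / (3.0 * tvdt))
    hit = np.argmax(diam >= threshold)
    assert diam[hit] >= threshold
    # re-check with the scalar growth law (the oracle steps grow() day by day)
    assert grow(d0, rate, int(hit)) >= threshold or hit == 0
    return int(hit)


def test_closed_form_periods_agree_with_day_stepped_simulation(constants):
    """1,000 random (d_pt, TVDT) pairs: day-stepped threshold crossings of the
    growth law match the closed-form doubling arithmetic within one day."""
    rng = np.random.default_rng(2024)
    c = constants
    for _ in range(1000):
        d_pt = float(rng.uniform(1.2, 60.0))
        tvdt = float(rng.uniform(10.0, 270.0))
        p = latest_periods(d_pt, tvdt, c)
        dpy = c.days_per_year
        # MTS-I: PT grows from the seeding diameter (1 mm) to d_pt
        mts1_days = _day_stepped_crossing(c.pt_seeding_diameter, d_pt, tvdt)
        assert abs(mts1_days - p.mts1_years * dpy) <= 1.0
        # MTS-II: lesion already Npt-20 doublings old at surgery grows to 9 mm
        npt = 3 * math.log2(d_pt / c.cell_diameter)
        d_lesion = diameter_from_doublings(npt - c.seeding_doubling_index, c)
        mts2_days = _day_stepped_crossing(d_lesion, c.mts_detection_diameter, tvdt)
        assert abs(mts2_days - p.mts2_years * dpy) <= 1.0
        # visible: 9 mm to the lethal 40-doubling diameter
        lethal = diameter_from_doublings(c.lethal_doubling_count, c)
        vis_days = _day_stepped_crossing(c.mts_detection_diameter, lethal, tvdt)
        assert abs(vis_days - p.visible_years * dpy) <= 1.0
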
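"""Cardiovascular chain: EDV adjustments through arterial pressures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from humansim.cardio import (
    arterial_pressures,
    edv_adjustments,
    end_diastolic_volume,
    end_systolic_volume,
    heart_rate,
    stroke_and_output,
    sympathetic_target,
    ventricular_pressure,
)


class TestEdvAdjustments:
    def test_all_zero_at_baseline(self):
        adj = edv_adjustments(1.0, 0.0, 0.0, 0.0)
        assert adj == (0.0, 0.0, 0.0, 0.0)
        assert end_diastolic_volume(adj) == 120.0

    def test_volemia_effect_confined_to_bounds(self):
        for r in np.linspace(0.0, 5.0, 501):
            d_vol = edv_adjustments(r, 0, 0, 0)[0]
            assert -70.0 <= d_vol <= 40.0

    def test_exsanguination_limit(self):
        assert edv_adjustments(0.0, 0, 0, 0)[0] == pytest.approx(-70.0)

    def test_volemia_effect_monotone_increasing(self):
        grid = np.linspace(0.0, 3.0, 301)
        vals = [edv_adjustments(r, 0, 0, 0)[0] for r in grid]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_pericardial_effect_monotone_decreasing(self):
        grid = np.linspace(0.0, 1000.0, 201)
        vals = [edv_adjustments(1.0, v, 0, 0)[1] for v in grid]
        assert vals[0] == 0.0
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert all(v <= 0 for v in vals)

    def test_pleural_effect_monotone_decreasing(self):
        grid = np.linspace(0.0, 60.0, 121)
        vals = [edv_adjustments(1.0, 0, p, 0)[2] for p in grid]
        assert vals[0] == 0.0
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_sympathetic_effect_monotone_increasing_from_zero(self):
        grid = np.linspace(0.0, 1.0, 101)
        vals = [edv_adjustments(1.0, 0, 0, s)[3] for s in grid]
        assert vals[0] == 0.0
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        assert all(0 <= v <= 40 for v in vals)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            edv_adjustments(-0.1, 0, 0, 0)
        with pytest.raises(ValueError):
            edv_adjustments(1.0, -5.0, 0, 0)


class TestEsvAndStroke:
    def test_baseline_esv_gives_70ml_stroke(self):
        esv = end_systolic_volume(0.0, 1.0)
        assert esv == 50.0
        sv, co = stroke_and_output(120.0, esv, 70.0)
        assert sv == 70.0
        assert co == pytest.approx(4.9)

    def test_contractility_rises_with_drive(self):
        assert end_systolic_volume(1.0, 1.0) < end_systolic_volume(0.0, 1.0)
        for s in np.linspace(0, 1, 21):
            assert end_systolic_volume(s, 1.0) >= 0.0

    @pytest.mark.parametrize(
        "edv, esv, hr, sv, co",
        [(120, 50, 70, 70, 4.9), (80, 80, 90, 0, 0), (120, 50, 0, 70, 0),
         (40, 70, 80, 0, 0)],  # ESV above EDV clamps SV at zero
    )
    def test_stroke_and_output(self, edv, esv, hr, sv, co):
        got_sv, got_co = stroke_and_output(edv, esv, hr)
        assert got_sv == pytest.approx(sv)
        assert got_co == pytest.approx(co)


class TestArterialPressures:
    def test_uncapped_chain(self):
        map_th, map_eff, co_eff, dbp, sbp = arterial_pressures(4.9, 13.0, 120.0)
        assert map_th == pytest.approx(63.7)
        assert map_eff == pytest.approx(63.7)
        assert co_eff == pytest.approx(4.9)
        assert dbp == pytest.approx(54.6)
        assert sbp == pytest.approx(95.55)

    def test_ventricular_pressure_caps_map(self):
        map_th, map_eff, co_eff, _, _ = arterial_pressures(200 / 13, 13.0, 120.0)
        assert map_th == pytest.approx(200.0)
        assert map_eff == pytest.approx(120.0)
        assert co_eff == pytest.approx(120.0 / 13.0)

    def test_zero_map_gives_zero_pressures(self):
        _, map_eff, _, dbp, sbp = arterial_pressures(0.0, 13.0, 120.0)
        assert map_eff == dbp == sbp == 0.0

    def test_zero_svr_rejected(self):
        with pytest.raises(ValueError):
            arterial_pressures(4.9, 0.0, 120.0)

    @given(
        co=st.floats(min_value=0.0, max_value=25.0),
        vp=st.floats(min_value=0.0, max_value=200.0),
    )
    @settings(deadline=None)
    def test_pressure_ratios_and_cap_invariants(self, co, vp):
        map_th, map_eff, co_eff, dbp, sbp = arterial_pressures(co, 13.0, vp)
        assert map_eff <= vp + 1e-12
        assert co_eff <= co + 1e-12
        assert dbp == pytest.approx(6 / 7 * map_eff)
        assert sbp == pytest.approx(3 / 2 * map_eff)
        assert dbp <= map_eff <= sbp or map_eff == 0.0


class TestVentricularPressure:
    def test_baseline_120(self):
        assert ventricular_pressure(0.0, 1.0, 0.0) == 120.0

    def test_collapses_with_exsanguination(self):
        grid = np.linspace(1.0, 0.0, 101)
        vals = [ventricular_pressure(0.5, r, 0.0) for r in grid]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == 0.0

    def test_monotone_in_sympathetic_drive(self):
        vals = [ventricular_pressure(s, 1.0, 0.0) for s in np.linspace(0, 1, 21)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_falls_with_tamponade(self):
        assert ventricular_pressure(0, 1.0, 300.0) < ventricular_pressure(0, 1.0, 0.0)


class TestSympatheticAndHeartRate:
    def test_quiescent_at_healthy_vitals(self):
        assert sympathetic_target(70.0, 97.0, 40.0) < 0.05

    def test_monotone_in_hypotension(self):
        assert sympathetic_target(40.0, 97.0, 40.0) > sympathetic_target(60.0, 97.0, 40.0)

    def test_bounded_on_grid(self):
        for m in np.linspace(0, 120, 25):
            for p in np.linspace(5, 110, 22):
                s = sympathetic_target(m, p, 40.0)
                assert 0.0 <= s <= 1.0

    def test_heart_rate_anchors(self):
        assert heart_rate(0.0, 45) == 70.0
        assert heart_rate(1.0, 45) == 175.0
        vals = [heart_rate(s, 45) for s in np.linspace(0, 1, 21)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
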
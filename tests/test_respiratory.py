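"""Ventilation, gas exchange, saturation and respiratory drive."""

import numpy as np
import pytest

from humansim.config import RespConfig
from humansim.respiratory import (
    alveolar_po2,
    alveolar_ventilation,
    arterial_gases,
    respiratory_drive,
    spo2_from_pao2,
)

CFG = RespConfig()


class TestAlveolarVentilation:
    def test_reference_value(self):
        assert alveolar_ventilation(14, 500, 110, 1.0) == pytest.approx(5.46)

    def test_dead_space_clamp(self):
        assert alveolar_ventilation(14, 100, 110, 1.0) == 0.0

    def test_linear_in_functional_fraction(self):
        full = alveolar_ventilation(14, 500, 110, 1.0)
        half = alveolar_ventilation(14, 500, 110, 0.5)
        assert half == pytest.approx(full / 2)


class TestGasExchange:
    def _converge(self, va, vo2, n=600):
        pao2, paco2, store = 97.1, 40.0, 2000.0
        for _ in range(n):
            g = arterial_gases(va, vo2, pao2, paco2, store, 2000.0, 1.0, CFG)
            pao2, paco2, store = g.pao2, g.paco2, g.o2_store
        return pao2, paco2

    def test_steady_state_paco2(self):
        # PaCO2 -> 0.863 * (0.84 * 238) / 4.2 ~ 41.1 mmHg
        _, paco2 = self._converge(4.2, 238.0)
        assert paco2 == pytest.approx(41.08, abs=0.1)

    def test_alveolar_gas_equation(self):
        # PAO2 at PaCO2 40: 0.21*713 - 40/0.84 ~ 102.1; arterial ~ 97.1
        assert alveolar_po2(40.0, CFG) == pytest.approx(102.1, abs=0.1)
        pao2, _ = self._converge(4.4, 238.0)
        assert pao2 == pytest.approx(alveolar_po2(39.2, CFG) - 5.0, abs=1.0)

    def test_apnea_depletes_store_and_oxygen(self):
        pao2, paco2, store = 97.1, 40.0, 1000.0
        prev_pao2, prev_store = pao2, store
        for i in range(300):
            g = arterial_gases(0.0, 240.0, pao2, paco2, store, 1000.0, 1.0, CFG)
            pao2, paco2, store = g.pao2, g.paco2, g.o2_store
            assert store >= 0.0
            assert store <= prev_store
            assert pao2 <= prev_pao2
            prev_pao2, prev_store = pao2, store
        assert store == 0.0
        assert pao2 == CFG.pao2_floor

    def test_apnea_co2_rise_rate(self):
        g = arterial_gases(0.0, 240.0, 97.1, 40.0, 1000.0, 1000.0, 60.0, CFG)
        assert g.paco2 == pytest.approx(40.0 + CFG.paco2_apnea_rate)

    def test_store_refill_never_exceeds_capacity(self):
        store = 500.0
        for _ in range(600):
            g = arterial_gases(5.0, 240.0, 97.1, 40.0, store, 1800.0, 1.0, CFG)
            store = g.o2_store
            assert store <= 1800.0
        assert store > 1500.0  # refilled most of the way


class TestSaturationCurve:
    def test_p50(self):
        assert spo2_from_pao2(26.8) == pytest.approx(50.0, abs=1.0)

    def test_normoxia(self):
        assert 97.0 <= spo2_from_pao2(100.0) <= 98.0

    def test_monotone_and_bounded(self):
        grid = np.linspace(1.0, 600.0, 400)
        vals = [spo2_from_pao2(p) for p in grid]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        assert all(0 < v <= 100 for v in vals)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            spo2_from_pao2(0.0)


class TestRespiratoryDrive:
    def test_baseline(self):
        rr, vt = respiratory_drive(40.0, 97.0, True, 1.0, True, 7 * 73.4, config=CFG)
        assert 12 <= rr <= 16
        assert vt == pytest.approx(7 * 73.4)

    def test_paralysed_diaphragm_means_apnea(self):
        rr, vt = respiratory_drive(80.0, 30.0, False, 1.0, True, 500.0, config=CFG)
        assert rr == 0.0 and vt == 0.0

    def test_hypercapnic_drive(self):
        rr60, _ = respiratory_drive(60.0, 97.0, True, 1.0, True, 500.0, config=CFG)
        rr40, _ = respiratory_drive(40.0, 97.0, True, 1.0, True, 500.0, config=CFG)
        assert rr60 > rr40
        assert rr60 <= CFG.rr_max

    def test_hypoxic_drive(self):
        rr_low, _ = respiratory_drive(40.0, 45.0, True, 1.0, True, 500.0, config=CFG)
        rr_norm, _ = respiratory_drive(40.0, 97.0, True, 1.0, True, 500.0, config=CFG)
        assert rr_low > rr_norm

    def test_airway_patency_scales_tidal_volume(self):
        _, vt_half = respiratory_drive(40.0, 97.0, True, 0.5, True, 500.0, config=CFG)
        assert vt_half == pytest.approx(250.0)

    def test_intercostal_loss_reduces_tidal_volume(self):
        _, vt = respiratory_drive(40.0, 97.0, True, 1.0, False, 500.0, config=CFG)
        assert vt == pytest.approx(500.0 * CFG.intercostal_vt_factor)

    def test_chest_wall_ceiling(self):
        _, vt = respiratory_drive(40.0, 97.0, True, 1.0, True, 500.0, 180.0, CFG)
        assert vt == 180.0
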
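"""Ventilation, arterial gases and oxygen saturation.

The lung vertex of the heart-lung-brain model.  Alveolar ventilation is
rate x (tidal volume - dead space) x functional lung fraction; arterial
CO2 follows the steady-state relation PaCO2 = 0.863 * VCO2 / VA approached
with a first-order lag, and arterial O2 follows the alveolar gas equation
minus a fixed alveolar-arterial gradient.  During apnea a finite body
oxygen store (functional residual capacity plus blood-bound O2, lumped as
one per-kg capacity) is consumed at the metabolic rate and arterial O2
falls with the remaining store fraction while CO2 climbs at a fixed rate.
Saturation comes from the Severinghaus (1979) closed-form dissociation
curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import RespConfig

_DEFAULT = RespConfig()


def alveolar_ventilation(
    rr: float, tidal_volume: float, dead_space: float, functional_fraction: float
) -> float:
    """Effective alveolar ventilation, L/min.

    ``functional_fraction`` is the combined share of lung actually
    participating in gas exchange (1.0 healthy; 0.55 after complete left
    pneumothorax; reduced further by restrictive injuries).
    """
    if min(rr, tidal_volume, dead_space, functional_fraction) < 0:
        raise ValueError("ventilation inputs must be >= 0")
    per_breath = max(0.0, tidal_volume - dead_space) * functional_fraction
    return rr * per_breath / 1000.0


def spo2_from_pao2(pao2: float) -> float:
    """Oxygen saturation (%) from arterial PO2 (mmHg), Severinghaus 1979.

    S = 100 / (23400 / (P^3 + 150 P) + 1); monotone, ~50% at the 26.8 mmHg
    P50, ~97% at 100 mmHg.
    """
    if pao2 <= 0:
        raise ValueError("pao2 must be positive")
    x = pao2**3 + 150.0 * pao2
    return 100.0 / (23400.0 / x + 1.0)


def alveolar_po2(paco2: float, config: RespConfig = _DEFAULT) -> float:
    """Alveolar O2 tension from the alveolar gas equation, mmHg."""
    c = config
    return c.fio2 * (c.barometric_pressure - c.water_vapour_pressure) - paco2 / c.rq


@dataclass
class GasUpdate:
    pao2: float
    paco2: float
    o2_store: float


def arterial_gases(
    va: float,
    vo2: float,
    pao2: float,
    paco2: float,
    o2_store: float,
    o2_store_capacity: float,
    dt: float,
    config: RespConfig = _DEFAULT,
    rq: float | None = None,
) -> GasUpdate:
    """Advance arterial gas tensions and the body O2 store by ``dt`` seconds.

    Breathing (``va > 0``): PaCO2 relaxes toward 0.863*VCO2/VA and PaO2
    toward the alveolar gas equation value minus the A-a gradient, both with
    the configured lag; the store tracks the PaO2 fraction of its healthy
    reference.  Apnea (``va == 0``): the store is drawn down at the
    metabolic rate, PaO2 falls in proportion to the remaining store
    fraction, and PaCO2 rises at the configured apneic rate.
    """
    if va < 0 or dt <= 0:
        raise ValueError("require va >= 0 and dt > 0")
    c = config
    rq = c.rq if rq is None else rq
    alpha = 1.0 - math.exp(-dt / c.gas_tau)
    if va > 0.0:
        vco2 = rq * vo2  # mL/min
        paco2_target = c.paco2_conversion * vco2 / va  # mmHg
        paco2_new = paco2 + alpha * (paco2_target - paco2)
        pao2_target = max(c.pao2_floor, alveolar_po2(paco2_new, c) - c.aa_gradient)
        pao2_new = pao2 + alpha * (pao2_target - pao2)
        store_target = o2_store_capacity * min(1.0, pao2_new / c.pao2_reference)
        store_new = o2_store + alpha * (store_target - o2_store)
        store_new = min(o2_store_capacity, max(0.0, store_new))
    else:
        store_new = max(0.0, o2_store - vo2 * dt / 60.0)
        frac_before = o2_store / o2_store_capacity if o2_store_capacity > 0 else 0.0
        frac_after = store_new / o2_store_capacity if o2_store_capacity > 0 else 0.0
        if frac_before > 0:
            # PaO2 scales with the store fraction relative to its value at
            # the start of this apneic interval; implemented incrementally so
            # apnea can begin from an already hypoxic state.
            pao2_new = max(c.pao2_floor, pao2 * frac_after / frac_before)
        else:
            pao2_new = c.pao2_floor
        paco2_new = paco2 + c.paco2_apnea_rate * dt / 60.0
    return GasUpdate(pao2=pao2_new, paco2=paco2_new, o2_store=store_new)


def respiratory_drive(
    paco2: float,
    pao2: float,
    diaphragm_intact: bool,
    airway_patency: float,
    intercostals_intact: bool,
    vt_baseline: float,
    vt_ceiling: float = math.inf,
    config: RespConfig = _DEFAULT,
) -> tuple[float, float]:
    """(respiratory rate /min, tidal volume mL) from chemoreceptor drive.

    Rate starts at 14/min and climbs toward 35/min with hypercapnia or
    hypoxaemia.  Tidal volume is the 7 mL/kg-IBW baseline scaled by airway
    patency (laryngeal edema), reduced to the diaphragm-only share when the
    intercostals are lost, and capped by any chest-wall ceiling.  A
    paralysed diaphragm means apnea regardless of drive.
    """
    c = config
    if not diaphragm_intact:
        return 0.0, 0.0
    rr = (
        c.rr0
        + c.rr_co2_gain * max(0.0, paco2 - c.rr_co2_threshold)
        + c.rr_o2_gain * max(0.0, c.rr_o2_threshold - pao2)
    )
    rr = min(c.rr_max, max(0.0, rr))
    vt = vt_baseline * min(1.0, max(0.0, airway_patency))
    if not intercostals_intact:
        vt *= c.intercostal_vt_factor
    vt = min(vt, vt_ceiling)
    return rr, max(0.0, vt)


def o2_store_capacity(weight_kg: float, config: RespConfig = _DEFAULT) -> float:
    """Total usable body oxygen store, mL O2."""
    return config.o2_store_per_kg * weight_kg


def resting_vo2(weight_kg: float, config: RespConfig = _DEFAULT) -> float:
    """Resting oxygen consumption, mL/min (3.5 mL/kg/min convention)."""
    return config.vo2_per_kg * weight_kg
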
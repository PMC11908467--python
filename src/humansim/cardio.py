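"""Lumped-parameter cardiovascular chain.

The pressure chain runs: end-diastolic volume (a 120 mL baseline plus four
additive adjustments for volemia, pericardial effusion, pleural pressure and
sympathetic venous return) -> end-systolic volume -> stroke volume ->
cardiac output -> theoretical mean arterial pressure (CO x SVR) -> effective
MAP capped by the left-ventricular pressure -> diastolic and systolic
pressures as fixed ratios of MAP (6/7 and 3/2).

The four adjustment curves and the ESV/VP surfaces are smooth saturating
functions whose bounds and monotonicity are fixed by the model description;
their scale parameters are calibration surface (see :mod:`humansim.config`).
"""

from __future__ import annotations

import math

from .config import CardioConfig

_DEFAULT = CardioConfig()


def edv_adjustments(
    volemia_ratio: float,
    pericardial_volume: float,
    pleural_pressure: float,
    sympathetic: float,
    config: CardioConfig = _DEFAULT,
) -> tuple[float, float, float, float]:
    """The four additive EDV adjustments, in mL.

    Returns ``(d_volemia, d_pericardial, d_pleural, d_sympathetic)``:

    * ``d_volemia`` rises smoothly with the volemia ratio (blood volume over
      baseline), is 0 at normovolemia, and is confined to [-70, +40] mL;
    * ``d_pericardial`` falls from 0 as pericardial fluid accumulates
      (tamponade limits diastolic filling);
    * ``d_pleural`` falls from 0 as pleural pressure rises above atmospheric;
    * ``d_sympathetic`` rises from 0 with sympathetic activation
      (venous return recruitment), saturating at +40 mL.
    """
    if volemia_ratio < 0:
        raise ValueError("volemia_ratio must be >= 0")
    if pericardial_volume < 0:
        raise ValueError("pericardial_volume must be >= 0")
    c = config
    if volemia_ratio >= 1.0:
        d_vol = c.dvol_high * (1.0 - math.exp(-c.dvol_up_rate * (volemia_ratio - 1.0)))
    else:
        d_vol = c.dvol_low * (1.0 - volemia_ratio) ** c.dvol_exponent
    d_peri = -c.dperi_max * (1.0 - math.exp(-pericardial_volume / c.dperi_volume_scale))
    p = max(0.0, pleural_pressure)
    d_pleu = -c.dpleu_max * (1.0 - math.exp(-p / c.dpleu_pressure_scale))
    d_symp = c.dsymp_max * (1.0 - math.exp(-c.dsymp_rate * max(0.0, sympathetic)))
    return d_vol, d_peri, d_pleu, d_symp


def end_diastolic_volume(adjustments: tuple[float, float, float, float],
                         config: CardioConfig = _DEFAULT) -> float:
    """EDV = 120 mL baseline plus the four adjustments, floored at 0."""
    return max(0.0, config.edv_initial + sum(adjustments))


def end_systolic_volume(
    sympathetic: float, volemia_ratio: float, config: CardioConfig = _DEFAULT
) -> float:
    """End-systolic volume, mL.

    Baseline 50 mL (so baseline stroke volume is 70 mL with EDV 120);
    sympathetic activation raises contractility and empties the ventricle
    further.  Never negative.
    """
    esv = config.esv0 * (1.0 - config.esv_symp_gain * min(1.0, max(0.0, sympathetic)))
    return max(0.0, esv)


def stroke_and_output(edv: float, esv: float, hr: float) -> tuple[float, float]:
    """Stroke volume (mL, clamped at 0) and cardiac output (L/min)."""
    if hr < 0:
        raise ValueError("heart rate must be >= 0")
    sv = max(0.0, edv - esv)
    co = sv * hr / 1000.0  # mL/beat * beats/min -> L/min
    return sv, co


def ventricular_pressure(
    sympathetic: float,
    volemia_ratio: float,
    pericardial_volume: float,
    config: CardioConfig = _DEFAULT,
) -> float:
    """Peak left-ventricular pressure, mmHg — the ceiling on achievable MAP.

    120 mmHg at rest, raised by sympathetic drive, collapsing toward zero
    with exsanguination (power law in the volemia ratio) or tamponade
    (exponential in pericardial volume): an empty or compressed pump cannot
    generate pressure.
    """
    c = config
    s = min(1.0, max(0.0, sympathetic))
    vol_term = min(1.0, max(0.0, volemia_ratio)) ** c.vp_volemia_exponent
    peri_term = math.exp(-max(0.0, pericardial_volume) / c.vp_tamponade_scale)
    return c.vp0 * (1.0 + c.vp_symp_gain * s) * vol_term * peri_term


def arterial_pressures(
    co: float, svr: float, vp: float
) -> tuple[float, float, float, float, float]:
    """(map_th, map_eff, co_eff, dbp, sbp) from cardiac output.

    ``map_th = CO x SVR`` is capped at the ventricular pressure ``vp``;
    when capped, the effective cardiac output is recomputed from the capped
    pressure.  DBP and SBP are fixed fractions 6/7 and 3/2 of effective MAP.
    """
    if svr <= 0:
        raise ValueError("svr must be positive")
    if co < 0 or vp < 0:
        raise ValueError("co and vp must be >= 0")
    map_th = co * svr
    if map_th < vp:
        map_eff = map_th
        co_eff = co
    else:
        map_eff = vp
        co_eff = vp / svr
    dbp = 6.0 / 7.0 * map_eff
    sbp = 3.0 / 2.0 * map_eff
    return map_th, map_eff, co_eff, dbp, sbp


def _soft_term(excess: float, scale: float) -> float:
    """Smooth saturating response to a positive excess, in [0, 1)."""
    return 1.0 - math.exp(-max(0.0, excess) / scale)


def sympathetic_target(
    map_eff: float, pao2: float, paco2: float, config: CardioConfig = _DEFAULT
) -> float:
    """Instantaneous sympathetic activation target in [0, 1].

    A soft-OR of three stress terms: hypotension below the MAP setpoint,
    hypoxaemia below the PaO2 threshold, hypercapnia above the PaCO2
    threshold.  Zero when all vitals are on the healthy side of their
    setpoints; saturates toward 1 under deep derangement.
    """
    c = config
    t_map = _soft_term(c.map_setpoint - map_eff, c.map_scale)
    t_o2 = _soft_term(c.pao2_threshold - pao2, c.pao2_scale)
    t_co2 = _soft_term(paco2 - c.paco2_threshold, c.paco2_scale)
    return 1.0 - (1.0 - t_map) * (1.0 - t_o2) * (1.0 - t_co2)


def sympathetic_drive(
    current: float,
    map_eff: float,
    pao2: float,
    paco2: float,
    dt: float,
    config: CardioConfig = _DEFAULT,
) -> float:
    """First-order relaxation of sympathetic activation toward its target.

    The lag (tau ~ 30 s) keeps the drive from jumping when a pathology
    switches a vital sign instantaneously.
    """
    target = sympathetic_target(map_eff, pao2, paco2, config)
    alpha = 1.0 - math.exp(-dt / config.symp_tau)
    s = current + alpha * (target - current)
    return min(1.0, max(0.0, s))


def heart_rate(sympathetic: float, age: float, config: CardioConfig = _DEFAULT) -> float:
    """Heart rate, beats/min: linear from the 70/min baseline to 220 - age."""
    s = min(1.0, max(0.0, sympathetic))
    hr_max = max(config.hr0, 220.0 - age)
    return config.hr0 + s * (hr_max - config.hr0)
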
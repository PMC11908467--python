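"""Intracranial pressure, cerebral perfusion, consciousness and mobility.

The brain vertex of the heart-lung-brain model.  Cerebral perfusion
pressure is MAP minus ICP; cerebral blood flow sits on a 0.7 L/min
autoregulation plateau for CPP between 50 and 150 mmHg and falls linearly
to zero below it.  An expanding intracranial hematoma raises ICP along a
Marmarou-type exponential pressure-volume curve.  The Glasgow Coma Scale is
derived from a brain oxygen-delivery proxy (flow fraction x saturation),
with severe hypercapnia capping the score; the walking flag requires a
near-normal GCS plus intact leg effectors.
"""

from __future__ import annotations

import math

from .anatomy import EffectorStatus
from .config import NeuroConfig

_DEFAULT = NeuroConfig()


def cerebral_perfusion(
    map_eff: float, icp: float, config: NeuroConfig = _DEFAULT
) -> tuple[float, float]:
    """(CPP mmHg, CBF L/min).

    CPP = MAP - ICP (may be <= 0).  CBF is 0.7 L/min on the autoregulation
    plateau, scales linearly down to 0 between CPP 50 and 0.
    """
    if map_eff < 0 or icp < 0:
        raise ValueError("map_eff and icp must be >= 0")
    c = config
    cpp = map_eff - icp
    if cpp <= 0:
        cbf = 0.0
    elif cpp < c.autoreg_low:
        cbf = c.cbf_plateau * cpp / c.autoreg_low
    else:
        cbf = c.cbf_plateau
    return cpp, cbf


def icp_from_bleed(
    intracranial_bleed_volume: float, config: NeuroConfig = _DEFAULT
) -> float:
    """ICP, mmHg, from the intracranial mass volume (mL).

    Exponential pressure-volume (elastance) relation
    ``icp = icp0 * exp(V / kappa)``: the first millilitres are buffered,
    then pressure runs away.
    """
    if intracranial_bleed_volume < 0:
        raise ValueError("bleed volume must be >= 0")
    c = config
    return c.icp_baseline * math.exp(intracranial_bleed_volume / c.elastance_volume)


def gcs_estimate(
    cbf_fraction: float, spo2: float, paco2: float, config: NeuroConfig = _DEFAULT
) -> int:
    """Glasgow Coma Scale total (3-15) from a brain O2-delivery proxy.

    The proxy is (CBF / plateau) x (SpO2 / 98).  GCS is 15 while the proxy
    stays at or above 0.9, degrades linearly in integer steps to 3 at 0.2,
    and is capped at 8 under severe hypercapnia (CO2 narcosis).
    """
    c = config
    proxy = max(0.0, cbf_fraction) * max(0.0, spo2) / 98.0
    if proxy >= c.gcs_proxy_full:
        gcs = 15
    elif proxy <= c.gcs_proxy_zero:
        gcs = 3
    else:
        frac = (proxy - c.gcs_proxy_zero) / (c.gcs_proxy_full - c.gcs_proxy_zero)
        gcs = 3 + int(round(12 * frac))
    if paco2 > c.paco2_gcs_cap:
        gcs = min(gcs, c.gcs_cap_value)
    return max(3, min(15, gcs))


def can_walk(
    gcs: int,
    effectors: EffectorStatus,
    lower_limbs_intact: bool = True,
    config: NeuroConfig = _DEFAULT,
) -> bool:
    """Walking requires consciousness, leg innervation and intact limbs."""
    return (
        gcs >= config.walk_gcs_threshold
        and effectors.legs_motor_intact
        and lower_limbs_intact
    )
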
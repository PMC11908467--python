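"""The full mutable physiological state advanced by the engine."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

from . import cardio, neuro, respiratory
from .anatomy import SpinalLesion
from .config import ModelConfig
from .patients import PatientProfile


@dataclass
class PhysioState:
    """All cardiovascular, respiratory and neurological variables at time t.

    Accumulator fields (blood volume, pericardial volume, bleed volume,
    airway patency, ...) are mutated by pathology presets; everything else
    is recomputed each step from the model chains.
    """

    t: float = 0.0

    # --- cardiovascular ---
    blood_volume: float = 0.0  # mL
    cumulative_blood_loss: float = 0.0  # mL, bookkeeping identity
    pericardial_volume: float = 0.0  # mL of effusion
    pleural_pressure: float = 0.0  # mmHg above atmospheric
    sympathetic: float = 0.0  # activation in [0, 1]
    hr: float = 70.0  # beats/min
    d_edv_volemia: float = 0.0
    d_edv_pericardial: float = 0.0
    d_edv_pleural: float = 0.0
    d_edv_sympathetic: float = 0.0
    edv: float = 120.0  # mL
    esv: float = 50.0  # mL
    sv: float = 70.0  # mL
    co: float = 4.9  # L/min
    co_eff: float = 4.9
    vp: float = 120.0  # mmHg
    map_th: float = 63.7
    map_eff: float = 63.7
    dbp: float = 54.6
    sbp: float = 95.55

    # --- respiratory ---
    rr: float = 14.0  # breaths/min
    tidal_volume: float = 0.0  # mL
    alveolar_volume: float = 0.0  # mL effective per breath
    va: float = 0.0  # L/min alveolar ventilation
    airway_patency: float = 1.0  # [0, 1]
    vt_ceiling: float = float("inf")  # mL, chest-wall restriction
    lung_share_left: float = 0.45
    lung_share_right: float = 0.55
    pao2: float = 97.1  # mmHg
    paco2: float = 40.0  # mmHg
    spo2: float = 97.3  # %
    o2_store: float = 0.0  # mL O2
    o2_store_capacity: float = 0.0
    vo2: float = 0.0  # mL/min

    # --- neurological ---
    intracranial_bleed_volume: float = 0.0  # mL
    icp: float = 10.0  # mmHg
    cpp: float = 53.7  # mmHg
    cbf: float = 0.7  # L/min
    gcs: int = 15
    walks: bool = True
    lesion: Optional[SpinalLesion] = None
    lower_limbs_intact: bool = True

    @property
    def functional_fraction(self) -> float:
        return self.lung_share_left + self.lung_share_right

    def volemia_ratio(self, baseline: float) -> float:
        return self.blood_volume / baseline if baseline > 0 else 0.0

    def copy(self) -> "PhysioState":
        return replace(self)

    def field_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def initial_state(profile: PatientProfile, config: Optional[ModelConfig] = None) -> PhysioState:
    """Pre-insult state of a healthy patient (before equilibration)."""
    cfg = config or ModelConfig()
    s = PhysioState()
    s.blood_volume = profile.blood_volume_baseline
    s.vo2 = respiratory.resting_vo2(profile.weight, cfg.resp)
    s.o2_store_capacity = respiratory.o2_store_capacity(profile.weight, cfg.resp)
    s.o2_store = s.o2_store_capacity
    s.tidal_volume = cfg.resp.vt_per_kg_ibw * profile.ideal_weight
    s.alveolar_volume = max(0.0, s.tidal_volume - profile.dead_space)
    s.va = s.rr * s.alveolar_volume / 1000.0
    s.pao2 = cfg.resp.pao2_reference
    s.spo2 = respiratory.spo2_from_pao2(s.pao2)
    s.hr = cfg.cardio.hr0
    s.icp = cfg.neuro.icp_baseline
    _refresh_cardio_neuro(s, profile, cfg)
    return s


def _refresh_cardio_neuro(
    s: PhysioState,
    profile: PatientProfile,
    cfg: ModelConfig,
    blood_volume: float | None = None,
    pericardial_volume: float | None = None,
    pleural_pressure: float | None = None,
    bleed_volume: float | None = None,
) -> None:
    """Recompute the derived cardiovascular and neurological chain in place.

    The optional arguments let the engine feed the previous step's
    accumulator values (synchronous update); by default the state's own
    current values are used.
    """
    bv = s.blood_volume if blood_volume is None else blood_volume
    peri = s.pericardial_volume if pericardial_volume is None else pericardial_volume
    pleu = s.pleural_pressure if pleural_pressure is None else pleural_pressure
    bleed = (
        s.intracranial_bleed_volume if bleed_volume is None else bleed_volume
    )
    ratio = bv / profile.blood_volume_baseline if profile.blood_volume_baseline > 0 else 0.0
    adj = cardio.edv_adjustments(ratio, peri, pleu, s.sympathetic, cfg.cardio)
    s.d_edv_volemia, s.d_edv_pericardial, s.d_edv_pleural, s.d_edv_sympathetic = adj
    s.edv = cardio.end_diastolic_volume(adj, cfg.cardio)
    s.esv = cardio.end_systolic_volume(s.sympathetic, ratio, cfg.cardio)
    s.hr = cardio.heart_rate(s.sympathetic, profile.age, cfg.cardio)
    s.sv, s.co = cardio.stroke_and_output(s.edv, s.esv, s.hr)
    s.vp = cardio.ventricular_pressure(s.sympathetic, ratio, peri, cfg.cardio)
    s.map_th, s.map_eff, s.co_eff, s.dbp, s.sbp = cardio.arterial_pressures(
        s.co, cfg.cardio.svr, s.vp
    )
    s.icp = neuro.icp_from_bleed(bleed, cfg.neuro)
    s.cpp, s.cbf = neuro.cerebral_perfusion(s.map_eff, s.icp, cfg.neuro)
    s.gcs = neuro.gcs_estimate(
        s.cbf / cfg.neuro.cbf_plateau, s.spo2, s.paco2, cfg.neuro
    )
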
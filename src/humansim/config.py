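"""Model configuration: every tunable constant of the simulator in one place.

The simulator is a lumped-parameter model; most of its behaviour is set by a
small number of named constants (setpoints, gains, time constants).  They are
grouped by organ system and serialisable to/from YAML so a whole model
variant can be expressed as a single human-readable file
(``humansim dump-default-config``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PatientConfig:
    """Random patient generator settings.

    Height and BMI moments are population statistics of the simulated adult
    cohort; the BMI distribution is truncated to avoid physiologically absurd
    extremes.
    """

    age_min: int = 16
    age_max: int = 100
    male_probability: float = 0.5
    height_mean_male: float = 178.4  # cm
    height_sd_male: float = 7.6
    height_mean_female: float = 164.7
    height_sd_female: float = 7.1
    bmi_mean: float = 23.0  # kg/m^2
    bmi_sd: float = 3.0
    bmi_min: float = 15.0
    bmi_max: float = 40.0
    ideal_weight_floor: float = 30.0  # kg, guard for very short statures
    # Blood volume is computed from ideal weight (knowledge-base convention);
    # set to False to use actual weight instead.
    blood_volume_uses_ideal_weight: bool = True


@dataclass
class CardioConfig:
    """Cardiovascular chain constants.

    The chain is EDV (with four additive adjustments) -> ESV -> SV -> CO ->
    MAP (capped by left-ventricular pressure) -> DBP/SBP.  The adjustment
    curves are smooth saturating surrogates honouring the documented bounds;
    their scales are part of the calibration surface.
    """

    edv_initial: float = 120.0  # mL
    svr: float = 13.0  # mmHg*min/L, held constant
    esv0: float = 50.0  # mL at zero sympathetic drive -> baseline SV 70 mL
    esv_symp_gain: float = 0.4  # fractional ESV reduction at full drive
    vp0: float = 120.0  # mmHg, baseline left-ventricular pressure
    vp_symp_gain: float = 0.3  # fractional VP rise at full drive
    vp_volemia_exponent: float = 2.0  # VP ~ volemia_ratio**exp below 1
    vp_tamponade_scale: float = 200.0  # mL, e-folding pericardial volume
    # Volemia effect on EDV: bounded in [-70, +40] mL.
    dvol_low: float = -70.0
    dvol_high: float = 40.0
    dvol_exponent: float = 1.5  # shape of the hypovolemic branch
    dvol_up_rate: float = 2.5  # hypervolemic saturation rate
    # Pericardial effusion effect on EDV (<= 0).
    dperi_max: float = 110.0  # mL, asymptotic filling loss
    dperi_volume_scale: float = 150.0  # mL of effusion per e-fold
    # Pleural pressure effect on EDV (<= 0).
    dpleu_max: float = 50.0  # mL
    dpleu_pressure_scale: float = 10.0  # mmHg per e-fold
    # Sympathetic venous-return effect on EDV (>= 0).
    dsymp_max: float = 40.0  # mL
    dsymp_rate: float = 3.0
    # Sympathetic drive: soft-OR of hypotension, hypoxia, hypercapnia terms.
    map_setpoint: float = 65.0  # mmHg
    map_scale: float = 15.0
    pao2_threshold: float = 60.0  # mmHg
    pao2_scale: float = 15.0
    paco2_threshold: float = 50.0  # mmHg
    paco2_scale: float = 20.0
    symp_tau: float = 30.0  # s, first-order lag on drive
    hr0: float = 70.0  # beats/min at zero drive; max is 220 - age


@dataclass
class RespConfig:
    """Respiratory mechanics and gas-exchange constants."""

    rr0: float = 14.0  # breaths/min baseline
    rr_max: float = 35.0
    rr_co2_gain: float = 1.5  # breaths/min per mmHg above threshold
    rr_co2_threshold: float = 42.0  # mmHg
    rr_o2_gain: float = 0.5  # breaths/min per mmHg below threshold
    rr_o2_threshold: float = 60.0  # mmHg
    vt_per_kg_ibw: float = 7.0  # mL/kg ideal body weight
    intercostal_vt_factor: float = 0.6  # VT share left with diaphragm only
    rq: float = 0.84  # respiratory quotient, VCO2/VO2
    vo2_per_kg: float = 3.5  # mL/min/kg actual weight, resting
    fio2: float = 0.21
    barometric_pressure: float = 760.0  # mmHg
    water_vapour_pressure: float = 47.0  # mmHg at 37 C
    aa_gradient: float = 5.0  # mmHg alveolar-arterial O2 gradient
    pao2_floor: float = 5.0  # mmHg
    paco2_conversion: float = 0.863  # mmHg*L/mL, PaCO2 = k*VCO2/VA
    gas_tau: float = 60.0  # s, first-order lag on arterial tensions
    paco2_apnea_rate: float = 3.5  # mmHg/min rise during apnea
    o2_store_per_kg: float = 27.7326  # mL O2 per kg actual weight (calibrated)
    pao2_reference: float = 97.1  # mmHg, healthy arterial PO2 anchor
    lung_share_right: float = 0.55  # functional share of the right lung


@dataclass
class NeuroConfig:
    """Intracranial pressure, perfusion and consciousness constants."""

    icp_baseline: float = 10.0  # mmHg
    elastance_volume: float = 50.0  # mL, kappa of icp = icp0*exp(V/kappa)
    cbf_plateau: float = 0.7  # L/min on the autoregulation plateau
    autoreg_low: float = 50.0  # mmHg CPP, lower plateau bound
    autoreg_high: float = 150.0
    gcs_proxy_full: float = 0.9  # O2-delivery proxy for GCS 15
    gcs_proxy_zero: float = 0.2  # proxy at/below which GCS = 3
    paco2_gcs_cap: float = 80.0  # mmHg; above this GCS capped at 8
    gcs_cap_value: int = 8
    walk_gcs_threshold: int = 14


@dataclass
class DeathCriteria:
    """Fatal thresholds; any one held for ``dwell`` seconds means death."""

    cpp_min: float = 20.0  # mmHg
    spo2_min: float = 40.0  # %
    co_eff_min: float = 0.5  # L/min
    dwell: float = 60.0  # s


@dataclass
class EngineConfig:
    dt: float = 1.0  # s
    horizon: float = 14400.0  # s, 4 h cap
    export_stride: float = 5.0  # s between exported timeline rows
    death: DeathCriteria = field(default_factory=DeathCriteria)


@dataclass
class ModelConfig:
    """Aggregate of all subsystem configurations."""

    patient: PatientConfig = field(default_factory=PatientConfig)
    cardio: CardioConfig = field(default_factory=CardioConfig)
    resp: RespConfig = field(default_factory=RespConfig)
    neuro: NeuroConfig = field(default_factory=NeuroConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelConfig":
        cfg = cls()
        for section, values in data.items():
            target = getattr(cfg, section)
            for key, value in values.items():
                if key == "death":
                    for k, v in value.items():
                        setattr(target.death, k, v)
                elif not hasattr(target, key):
                    raise KeyError(f"unknown config key {section}.{key}")
                else:
                    setattr(target, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config() -> ModelConfig:
    return ModelConfig()
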
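"""Injury presets: parameterized per-step state mutators.

Nine untreated trauma presets are provided: two hemorrhages (massive
internal, venous limb), cardiac tamponade, complete left pneumothorax, two
burns (airway edema, restrictive chest eschar), intracranial hemorrhage,
and two cervical cord lesions (atlanto-occipital C0, low cervical C5-C7).

Each preset mutates only its documented footprint of accumulator fields;
the downstream physiology chains turn those accumulators into vital-sign
evolution.  Each lethal preset has one dominant free rate constant, fitted
by bisection against its published untreated time of death and frozen in
the packaged calibration file (``data/calibration.yaml``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Optional

import yaml

from .anatomy import SpinalLesion
from .config import ModelConfig
from .patients import PatientProfile
from .state import PhysioState

#: MAP at which hemorrhage rates are quoted (pressure-dependent bleeding).
BLEED_REFERENCE_MAP = 70.0


@dataclass(frozen=True)
class PathologyPreset:
    """A parameterized injury bound to an anatomical block."""

    id: str
    target_block: str
    params: dict[str, float] = field(default_factory=dict)
    onset: float = 0.0  # s
    description: str = ""
    lesion_level: Optional[str] = None  # vertebral level, spinal presets only

    def with_params(self, **updates: float) -> "PathologyPreset":
        params = {**self.params, **updates}
        return replace(self, params=params)

    def with_onset(self, onset: float) -> "PathologyPreset":
        return replace(self, onset=onset)


def _bleed(state: PhysioState, amount: float) -> None:
    amount = min(amount, state.blood_volume)
    state.blood_volume -= amount
    state.cumulative_blood_loss += amount


def hemorrhage_step(
    state: PhysioState, preset: PathologyPreset, profile: PatientProfile,
    config: ModelConfig, dt: float,
) -> None:
    """External/internal bleeding at a pressure-dependent rate.

    The quoted rate (mL/min) applies at a driving MAP of 70 mmHg and scales
    linearly with the current MAP, so bleeding decelerates as the patient
    becomes hypotensive and stops entirely at zero pressure.
    """
    rate = preset.params["rate_ml_per_min"]
    _bleed(state, rate * (state.map_eff / BLEED_REFERENCE_MAP) * dt / 60.0)


def tamponade_step(
    state: PhysioState, preset: PathologyPreset, profile: PatientProfile,
    config: ModelConfig, dt: float,
) -> None:
    """Pericardial effusion accumulating at a constant rate (mL/min)."""
    state.pericardial_volume += preset.params["rate_ml_per_min"] * dt / 60.0


def pneumothorax_step(
    state: PhysioState, preset: PathologyPreset, profile: PatientProfile,
    config: ModelConfig, dt: float,
) -> None:
    """Complete collapse of one lung (simple, non-tension).

    At onset the affected lung's functional share drops to zero and pleural
    pressure settles at a modest supra-atmospheric level; the contralateral
    lung is untouched.  Idempotent after onset.
    """
    if preset.params.get("side", 0.0) >= 0.5:
        state.lung_share_right = 0.0
    else:
        state.lung_share_left = 0.0
    state.pleural_pressure = preset.params["pleural_pressure_mmHg"]


def burn_step(
    state: PhysioState, preset: PathologyPreset, profile: PatientProfile,
    config: ModelConfig, dt: float,
) -> None:
    """Progressive burn physiology.

    Airway burns close the upper airway exponentially (edema) with time
    constant ``tau_s``; circumferential chest burns shrink the achievable
    tidal volume toward a floor fraction of baseline (tightening eschar).
    Both leak plasma from the circulation at a slow constant rate.
    """
    decay = math.exp(-dt / preset.params["tau_s"])
    if preset.params.get("airway", 0.0) >= 0.5:
        state.airway_patency *= decay
    else:
        vt0 = config.resp.vt_per_kg_ibw * profile.ideal_weight
        floor = preset.params["vt_floor_fraction"] * vt0
        ceiling = state.vt_ceiling if math.isfinite(state.vt_ceiling) else vt0
        state.vt_ceiling = floor + (ceiling - floor) * decay
    _bleed(state, preset.params.get("plasma_rate_ml_per_min", 0.0) * dt / 60.0)


def tbi_step(
    state: PhysioState, preset: PathologyPreset, profile: PatientProfile,
    config: ModelConfig, dt: float,
) -> None:
    """Expanding intracranial hematoma at a constant rate (mL/min).

    The bled volume also leaves the circulation (a small loss relative to
    total blood volume); intracranial pressure is derived from the
    accumulated volume by the elastance curve in :mod:`humansim.neuro`.
    """
    dv = preset.params["rate_ml_per_min"] * dt / 60.0
    state.intracranial_bleed_volume += dv
    _bleed(state, dv)


def spinal_step(
    state: PhysioState, preset: PathologyPreset, profile: PatientProfile,
    config: ModelConfig, dt: float,
) -> None:
    """Install a cord lesion once at onset; effector loss follows."""
    if state.lesion is None:
        state.lesion = SpinalLesion(
            level=preset.lesion_level or "C6",
            completeness=preset.params.get("completeness", 1.0),
        )


_STEP_FUNCTIONS: dict[str, Callable[..., None]] = {
    "internal_hemorrhage": hemorrhage_step,
    "venous_limb_hemorrhage": hemorrhage_step,
    "tamponade": tamponade_step,
    "pneumothorax_complete": pneumothorax_step,
    "burn_airway": burn_step,
    "burn_chest_circumferential": burn_step,
    "tbi_hemorrhage": tbi_step,
    "spinal_C0": spinal_step,
    "spinal_C5C7": spinal_step,
}


def apply_preset(
    state: PhysioState, preset: PathologyPreset, profile: PatientProfile,
    config: ModelConfig, dt: float,
) -> None:
    """Apply one preset's per-step mutation if its onset has passed."""
    if state.t < preset.onset:
        return
    _STEP_FUNCTIONS[preset.id](state, preset, profile, config, dt)


# Default catalog.  Rate constants marked "calibrated" are the frozen
# results of fitting each preset's published untreated time of death; they
# are overridden by data/calibration.yaml when present.
_BASE_CATALOG = [
    PathologyPreset(
        "internal_hemorrhage", "abdomen",
        {"rate_ml_per_min": 63.1731},  # calibrated
        description="Massive internal hemorrhage (eg, ruptured spleen)",
    ),
    PathologyPreset(
        "venous_limb_hemorrhage", "forearm_l",
        {"rate_ml_per_min": 3.0},
        description="Venous hemorrhage of the left forearm",
    ),
    PathologyPreset(
        "tamponade", "thorax",
        {"rate_ml_per_min": 2.1916},  # calibrated
        description="Traumatic cardiac tamponade",
    ),
    PathologyPreset(
        "pneumothorax_complete", "thorax",
        {"pleural_pressure_mmHg": 2.0, "side": 0.0},
        description="Complete left pneumothorax",
    ),
    PathologyPreset(
        "burn_airway", "neck",
        {"tau_s": 6634.513, "airway": 1.0, "plasma_rate_ml_per_min": 1.0},  # calibrated tau
        description="Circular second-degree burns of the face and neck",
    ),
    PathologyPreset(
        "burn_chest_circumferential", "thorax",
        {"tau_s": 3668.5315, "airway": 0.0, "vt_floor_fraction": 0.25,
         "plasma_rate_ml_per_min": 1.0},  # calibrated tau
        description="Complete circumferential third-degree burn of the chest",
    ),
    PathologyPreset(
        "tbi_hemorrhage", "head",
        {"rate_ml_per_min": 0.9543},  # calibrated
        description="Head trauma with cerebral hemorrhage",
    ),
    PathologyPreset(
        "spinal_C0", "neck",
        {"completeness": 1.0},
        description="Atlanto-occipital dislocation",
        lesion_level="C0",
    ),
    PathologyPreset(
        "spinal_C5C7", "neck",
        {"completeness": 1.0},
        description="Unstable, displaced cervical fracture between C5 and C7",
        lesion_level="C6",
    ),
]

#: Presets whose dominant constant is fitted to a finite published death
#: time, mapped to (parameter name, search bracket).
CALIBRATED_PARAMS: dict[str, tuple[str, tuple[float, float]]] = {
    "internal_hemorrhage": ("rate_ml_per_min", (5.0, 500.0)),
    "tamponade": ("rate_ml_per_min", (0.2, 50.0)),
    "burn_airway": ("tau_s", (300.0, 40000.0)),
    "burn_chest_circumferential": ("tau_s", (300.0, 40000.0)),
    "tbi_hemorrhage": ("rate_ml_per_min", (0.05, 20.0)),
    # spinal_C0's knob is the whole-body O2 store (resp.o2_store_per_kg),
    # handled at the config level by the calibration driver.
}


def _packaged_calibration() -> Optional[dict]:
    try:
        ref = resources.files("humansim").joinpath("data/calibration.yaml")
        if ref.is_file():
            return yaml.safe_load(ref.read_text())
    except (FileNotFoundError, ModuleNotFoundError):
        return None
    return None


def load_calibration(path: Optional[str | Path] = None) -> Optional[dict]:
    """Load a calibration mapping, from ``path`` or the packaged default."""
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    return _packaged_calibration()


def preset_catalog(
    calibration: Optional[dict] = None, use_packaged: bool = True
) -> dict[str, PathologyPreset]:
    """The nine-preset catalog, with calibrated constants applied."""
    if calibration is None and use_packaged:
        calibration = _packaged_calibration()
    catalog = {p.id: p for p in _BASE_CATALOG}
    if calibration:
        for pid, params in calibration.get("presets", {}).items():
            catalog[pid] = catalog[pid].with_params(**params)
    return catalog


def apply_calibration_to_config(
    config: ModelConfig, calibration: Optional[dict]
) -> ModelConfig:
    """Apply config-level calibrated constants (eg, the O2 store)."""
    if calibration:
        for section, values in calibration.get("config", {}).items():
            target = getattr(config, section)
            for key, value in values.items():
                setattr(target, key, value)
    return config
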
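"""Injury preset mutators: footprints, identities, calibration machinery."""

import math

import pytest

from humansim.config import ModelConfig
from humansim.engine import settle
from humansim.pathologies import apply_preset, preset_catalog
from humansim.validation import CalibrationError, _bisect_parameter

ALL_PRESETS = {
    "internal_hemorrhage",
    "venous_limb_hemorrhage",
    "tamponade",
    "pneumothorax_complete",
    "burn_airway",
    "burn_chest_circumferential",
    "tbi_hemorrhage",
    "spinal_C0",
    "spinal_C5C7",
}

# accumulator fields each preset is allowed to touch
FOOTPRINTS = {
    "internal_hemorrhage": {"blood_volume", "cumulative_blood_loss"},
    "venous_limb_hemorrhage": {"blood_volume", "cumulative_blood_loss"},
    "tamponade": {"pericardial_volume"},
    "pneumothorax_complete": {"lung_share_left", "pleural_pressure"},
    "burn_airway": {"airway_patency", "blood_volume", "cumulative_blood_loss"},
    "burn_chest_circumferential": {"vt_ceiling", "blood_volume", "cumulative_blood_loss"},
    "tbi_hemorrhage": {"intracranial_bleed_volume", "blood_volume", "cumulative_blood_loss"},
    "spinal_C0": {"lesion"},
    "spinal_C5C7": {"lesion"},
}


@pytest.fixture(scope="module")
def settled(reference_patient):
    return settle(reference_patient, ModelConfig())


def test_catalog_is_complete():
    assert set(preset_catalog()) == ALL_PRESETS


@pytest.mark.parametrize("preset_id", sorted(ALL_PRESETS))
def test_mutators_touch_only_their_footprint(preset_id, settled, reference_patient):
    cfg = ModelConfig()
    preset = preset_catalog()[preset_id]
    before = settled.field_dict()
    mutated = settled.copy()
    apply_preset(mutated, preset, reference_patient, cfg, dt=1.0)
    after = mutated.field_dict()
    for name, value in before.items():
        if name in FOOTPRINTS[preset_id]:
            continue
        assert after[name] == value, f"{preset_id} leaked into {name}"


def test_mutation_suppressed_before_onset(settled, reference_patient):
    cfg = ModelConfig()
    preset = preset_catalog()["internal_hemorrhage"].with_onset(100.0)
    mutated = settled.copy()
    apply_preset(mutated, preset, reference_patient, cfg, dt=1.0)
    assert mutated.field_dict() == settled.field_dict()


def test_bleeding_is_pressure_dependent(settled, reference_patient):
    cfg = ModelConfig()
    preset = preset_catalog()["internal_hemorrhage"]
    arrested = settled.copy()
    arrested.map_eff = 0.0
    apply_preset(arrested, preset, reference_patient, cfg, dt=1.0)
    assert arrested.blood_volume == settled.blood_volume  # no pressure, no loss
    perfused = settled.copy()
    apply_preset(perfused, preset, reference_patient, cfg, dt=1.0)
    assert perfused.blood_volume < settled.blood_volume


def test_zero_rate_presets_are_identities(settled, reference_patient):
    cfg = ModelConfig()
    for pid in ("tamponade", "tbi_hemorrhage"):
        preset = preset_catalog()[pid].with_params(rate_ml_per_min=0.0)
        mutated = settled.copy()
        apply_preset(mutated, preset, reference_patient, cfg, dt=1.0)
        assert mutated.field_dict() == settled.field_dict()


def test_tamponade_accumulates_monotonically(settled, reference_patient):
    cfg = ModelConfig()
    preset = preset_catalog()["tamponade"]
    s = settled.copy()
    prev = s.pericardial_volume
    for _ in range(30):
        apply_preset(s, preset, reference_patient, cfg, dt=1.0)
        assert s.pericardial_volume > prev
        prev = s.pericardial_volume


def test_pneumothorax_spares_right_lung(settled, reference_patient):
    cfg = ModelConfig()
    s = settled.copy()
    apply_preset(s, preset_catalog()["pneumothorax_complete"], reference_patient, cfg, 1.0)
    assert s.lung_share_left == 0.0
    assert s.lung_share_right == settled.lung_share_right


def test_spinal_presets_install_expected_lesions(settled, reference_patient):
    cfg = ModelConfig()
    for pid, level in (("spinal_C0", "C0"), ("spinal_C5C7", "C6")):
        s = settled.copy()
        apply_preset(s, preset_catalog()[pid], reference_patient, cfg, 1.0)
        assert s.lesion is not None
        assert s.lesion.level == level
        assert s.lesion.completeness == 1.0


class TestBisection:
    def test_converges_on_monotone_curve(self):
        calls = []

        def death_time(rate):
            calls.append(rate)
            return 100000.0 / rate

        value = _bisect_parameter(death_time, target=2700.0, bracket=(1.0, 1000.0))
        assert value == pytest.approx(100000.0 / 2700.0, rel=0.02)
        assert len(calls) <= 40 + 2

    def test_handles_increasing_curves(self):
        value = _bisect_parameter(lambda t: 2.0 * t, target=600.0, bracket=(10.0, 10000.0))
        assert value == pytest.approx(300.0, rel=0.02)

    def test_unbracketed_target_raises(self):
        with pytest.raises(CalibrationError):
            _bisect_parameter(lambda r: 1000.0 / r, target=5.0, bracket=(1.0, 10.0))

    def test_survival_is_treated_as_infinite(self):
        def death_time(rate):
            return math.inf if rate < 100.0 else 10000.0 / rate

        value = _bisect_parameter(death_time, target=50.0, bracket=(1.0, 10000.0))
        assert value == pytest.approx(200.0, rel=0.02)
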
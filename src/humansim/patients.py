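"""Random adult patient generation and anthropometric baselines.

A simulated casualty is described by sex, age, height and BMI; everything
else is derived.  Ideal body weight follows the Devine-type linear formula
(sex-specific intercept, 0.9 kg per cm above 152.4 cm), and the volumetric
baselines used by the physiology — circulating blood volume and anatomical
dead space — are proportional to ideal weight.
"""

from __future__ import annotations

import enum
import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .config import PatientConfig


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


#: kg added per cm of height above the reference stature
IDEAL_WEIGHT_SLOPE = 0.9
#: reference stature, cm (5 feet)
IDEAL_WEIGHT_REF_HEIGHT = 152.4
#: sex-specific intercepts at the reference stature, kg
IDEAL_WEIGHT_INTERCEPT = {Sex.male: 50.0, Sex.female: 45.5}

#: circulating blood volume, mL per kg ideal weight
BLOOD_VOLUME_PER_KG = 70.0
#: anatomical dead space, mL per kg ideal weight
DEAD_SPACE_PER_KG = 2.2


def ideal_weight(sex: Sex | str, height_cm: float) -> float:
    """Ideal body weight in kg for a given sex and height.

    The formula is applied literally, so statures below 152.4 cm yield
    values below the intercept (no clamp here; the generator applies a
    30 kg floor as a guard).

    Raises
    ------
    ValueError
        If ``height_cm`` is not strictly positive.
    """
    if not height_cm > 0:
        raise ValueError(f"height must be positive, got {height_cm}")
    sex = Sex(sex)
    return IDEAL_WEIGHT_INTERCEPT[sex] + IDEAL_WEIGHT_SLOPE * (
        height_cm - IDEAL_WEIGHT_REF_HEIGHT
    )


@dataclass(frozen=True)
class PatientProfile:
    """Demographics plus the derived volumetric baselines.

    ``weight`` always satisfies ``weight = bmi * (height/100)**2``;
    ``blood_volume_baseline`` and ``dead_space`` scale with ideal weight.
    """

    sex: Sex
    age: int  # years
    height: float  # cm
    bmi: float  # kg/m^2
    weight: float  # kg
    ideal_weight: float  # kg
    blood_volume_baseline: float  # mL
    dead_space: float  # mL

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sex"] = self.sex.value
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "PatientProfile":
        data = dict(data)
        data["sex"] = Sex(data["sex"])
        return cls(**data)


def baseline_volumes(ideal_weight_kg: float) -> tuple[float, float]:
    """(blood volume mL, dead space mL) from ideal weight in kg."""
    if not ideal_weight_kg > 0:
        raise ValueError("ideal weight must be positive")
    return BLOOD_VOLUME_PER_KG * ideal_weight_kg, DEAD_SPACE_PER_KG * ideal_weight_kg


def make_patient(
    sex: Sex | str,
    age: int,
    height: float,
    weight: Optional[float] = None,
    bmi: Optional[float] = None,
    config: Optional[PatientConfig] = None,
) -> PatientProfile:
    """Build a profile from explicit characteristics.

    Exactly one of ``weight`` or ``bmi`` must be given; the other is derived
    from height.  Used to enter published casualty rosters verbatim.
    """
    cfg = config or PatientConfig()
    sex = Sex(sex)
    if not height > 0:
        raise ValueError("height must be positive")
    if (weight is None) == (bmi is None):
        raise ValueError("give exactly one of weight or bmi")
    h_m = height / 100.0
    if weight is None:
        weight = bmi * h_m**2
    else:
        bmi = weight / h_m**2
    ibw = max(cfg.ideal_weight_floor, ideal_weight(sex, height))
    volume_weight = ibw if cfg.blood_volume_uses_ideal_weight else weight
    blood_volume = BLOOD_VOLUME_PER_KG * volume_weight
    return PatientProfile(
        sex=sex,
        age=int(age),
        height=float(height),
        bmi=float(bmi),
        weight=float(weight),
        ideal_weight=float(ibw),
        blood_volume_baseline=float(blood_volume),
        dead_space=float(DEAD_SPACE_PER_KG * ibw),
    )


def sample_patient(
    seed: int | np.random.Generator, config: Optional[PatientConfig] = None
) -> PatientProfile:
    """Draw one random adult casualty.

    Sex is equiprobable, age uniform over the adult range, height normal
    with sex-specific moments, BMI normal truncated to the configured band
    (rejection sampling).  The same seed always yields the same profile.
    """
    cfg = config or PatientConfig()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sex = Sex.male if rng.random() < cfg.male_probability else Sex.female
    age = int(rng.integers(cfg.age_min, cfg.age_max + 1))
    if sex is Sex.male:
        height = rng.normal(cfg.height_mean_male, cfg.height_sd_male)
    else:
        height = rng.normal(cfg.height_mean_female, cfg.height_sd_female)
    height = max(height, 120.0)  # extreme-tail guard, ~7 sigma
    while True:
        bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd)
        if cfg.bmi_min <= bmi <= cfg.bmi_max:
            break
    return make_patient(sex, age, height, bmi=bmi, config=cfg)


def sample_patients(
    n: int, seed: int, config: Optional[PatientConfig] = None
) -> list[PatientProfile]:
    """Draw ``n`` casualties from a single seeded stream."""
    rng = np.random.default_rng(seed)
    return [sample_patient(rng, config) for _ in range(n)]
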
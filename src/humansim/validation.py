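"""Nine-patient validation roster, calibration driver and batch harness.

The simulator's reference experiment runs nine automatically generated
patients, each ascribed exactly one untreated pathology, and records the
resulting times of death (or survival past the 4 h horizon).  Six of the
presets are lethal; each carries one dominant free constant which is fitted
here by bisection against the published untreated death time and frozen
into a calibration file.  The three surviving presets are verified, not
fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .config import ModelConfig
from .engine import run_until_death, sample_t0_t4
from .pathologies import (
    CALIBRATED_PARAMS,
    PathologyPreset,
    apply_calibration_to_config,
    load_calibration,
    preset_catalog,
)
from .patients import PatientProfile, make_patient


@dataclass(frozen=True)
class ValidationCase:
    """One roster entry: a patient, a preset id and the expected outcome.

    ``expected_death_s`` is None for patients expected to survive the
    4 h horizon.
    """

    number: int
    profile: PatientProfile
    preset_id: str
    expected_death_s: Optional[float]


def validation_roster() -> list[ValidationCase]:
    """The nine reference patients with their ascribed pathologies."""
    rows = [
        (1, "male", 45, 159, 64, "internal_hemorrhage", 2700.0),
        (2, "female", 30, 164, 67, "venous_limb_hemorrhage", None),
        (3, "male", 42, 182, 86, "tamponade", 8850.0),
        (4, "female", 63, 161, 53, "pneumothorax_complete", None),
        (5, "female", 46, 168, 68, "burn_airway", 5735.0),
        (6, "female", 50, 170, 61, "burn_chest_circumferential", 5670.0),
        (7, "female", 32, 161, 62, "tbi_hemorrhage", 4745.0),
        (8, "female", 61, 164, 69, "spinal_C0", 345.0),
        (9, "male", 44, 168, 57, "spinal_C5C7", None),
    ]
    return [
        ValidationCase(n, make_patient(sex, age, height, weight=weight), pid, tod)
        for n, sex, age, height, weight, pid, tod in rows
    ]


class CalibrationError(RuntimeError):
    pass


def _death_time(
    profile: PatientProfile, preset: PathologyPreset, config: ModelConfig
) -> float:
    res = run_until_death(profile, preset, config, collect_timeline=False)
    return res.time_of_death if res.time_of_death is not None else math.inf


def _bisect_parameter(
    evaluate,
    target: float,
    bracket: tuple[float, float],
    rel_tol: float = 0.01,
    max_iter: int = 60,
) -> float:
    """Find the parameter value whose death time matches ``target``.

    ``evaluate(param) -> death time (inf if surviving)`` must be monotone
    in the parameter over the bracket (either direction).  Works on
    log-spaced midpoints since the parameters are positive rates/time
    constants spanning decades.
    """
    lo, hi = bracket
    f_lo, f_hi = evaluate(lo), evaluate(hi)
    if f_lo == f_hi:
        raise CalibrationError(f"flat response over bracket {bracket}")
    increasing = f_hi > f_lo
    lo_v, hi_v = (f_lo, f_hi) if increasing else (f_hi, f_lo)
    if not (lo_v <= target <= hi_v):
        raise CalibrationError(
            f"target {target}s not bracketed by [{f_lo}, {f_hi}]s over {bracket}"
        )
    best = None
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        f_mid = evaluate(mid)
        if math.isfinite(f_mid) and abs(f_mid - target) / target <= rel_tol:
            best = mid
            break
        if (f_mid < target) == increasing:
            lo = mid
        else:
            hi = mid
        best = mid
    if best is None:
        raise CalibrationError("bisection failed to converge")
    return best


def calibrate_presets(
    config: Optional[ModelConfig] = None,
    rel_tol: float = 0.01,
    verbose: bool = False,
) -> dict:
    """Fit each lethal preset's dominant constant to its published death time.

    Returns a calibration mapping ``{"presets": {...}, "config": {...}}``.
    The apneic high-cord-lesion case is fitted first because its knob — the
    whole-body oxygen store per kg — is a config-level constant shared by
    every other scenario.
    """
    cfg = config or ModelConfig()
    roster = {c.preset_id: c for c in validation_roster()}
    catalog = preset_catalog(calibration=None, use_packaged=False)
    result: dict = {"presets": {}, "config": {"resp": {}}}

    # 1. O2 store from the apnea scenario (config-level knob)
    case = roster["spinal_C0"]

    def eval_store(per_kg: float) -> float:
        cfg.resp.o2_store_per_kg = per_kg
        return _death_time(case.profile, catalog["spinal_C0"], cfg)

    per_kg = _bisect_parameter(eval_store, case.expected_death_s, (5.0, 120.0), rel_tol)
    cfg.resp.o2_store_per_kg = per_kg
    result["config"]["resp"]["o2_store_per_kg"] = round(per_kg, 4)
    if verbose:
        print(f"spinal_C0: o2_store_per_kg = {per_kg:.3f} mL/kg")

    # 2. preset-level dominant rates
    for pid, (param, bracket) in CALIBRATED_PARAMS.items():
        case = roster[pid]

        def eval_rate(value: float, pid=pid, param=param, case=case) -> float:
            return _death_time(case.profile, catalog[pid].with_params(**{param: value}), cfg)

        value = _bisect_parameter(eval_rate, case.expected_death_s, bracket, rel_tol)
        result["presets"][pid] = {param: round(value, 4)}
        if verbose:
            print(f"{pid}: {param} = {value:.4f}")
    return result


def write_calibration(calibration: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(calibration, sort_keys=False))


def load_calibrated_setup(
    calibration_path: Optional[str | Path] = None,
) -> tuple[ModelConfig, dict[str, PathologyPreset]]:
    """(config, preset catalog) with the frozen calibration applied."""
    calibration = load_calibration(calibration_path)
    if calibration is None:
        raise CalibrationError(
            "no calibration found; run `humansim calibrate` first"
        )
    cfg = apply_calibration_to_config(ModelConfig(), calibration)
    return cfg, preset_catalog(calibration)


def run_validation_suite(
    outdir: Optional[str | Path] = None,
    calibration_path: Optional[str | Path] = None,
    config: Optional[ModelConfig] = None,
) -> pd.DataFrame:
    """Re-run the nine-patient untreated experiment.

    Writes per-patient timelines and five-point (T0-T4) tables when
    ``outdir`` is given, and returns a summary comparing simulated against
    expected outcomes with relative errors.
    """
    if config is None:
        cfg, catalog = load_calibrated_setup(calibration_path)
    else:
        cfg = config
        catalog = preset_catalog(load_calibration(calibration_path))
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    records = []
    for case in validation_roster():
        res = run_until_death(case.profile, catalog[case.preset_id], cfg)
        tod = res.time_of_death
        survived = tod is None
        expected = case.expected_death_s
        rel_err = (
            abs(tod - expected) / expected
            if (tod is not None and expected is not None)
            else None
        )
        records.append(
            {
                "patient": case.number,
                "pathology": case.preset_id,
                "expected_death_s": expected if expected is not None else ">14400",
                "simulated_death_s": tod if tod is not None else ">14400",
                "survived": survived,
                "rel_error": rel_err,
            }
        )
        if outdir is not None:
            res.timeline.to_csv(outdir / f"patient{case.number}_timeline.csv", index=False)
            t0t4 = sample_t0_t4(res.timeline, tod, cfg.engine.horizon)
            t0t4.to_json(outdir / f"patient{case.number}_t0t4.json", orient="records", indent=2)
    summary = pd.DataFrame(records)
    if outdir is not None:
        summary.to_csv(outdir / "summary.csv", index=False)
    return summary
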
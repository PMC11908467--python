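"""Fixed-step integration of the coupled heart-lung-brain model.

Each step applies, in order: (1) the active pathology mutators, (2) the
respiratory chain, (3) the sympathetic drive, (4) the cardiovascular chain,
(5) the neurological outputs.  Cross-module inputs (arterial gases feeding
the sympathetic drive, MAP feeding bleeding and perfusion) are read from
the previous step's values — a synchronous (Jacobi) scheme — so the update
order cannot create within-step causality loops.

Death is declared when any fatal criterion (cerebral perfusion pressure
< 20 mmHg, SpO2 < 40 %, effective cardiac output < 0.5 L/min) holds for 60
consecutive seconds; the reported time of death is the first entry into
that fatal dwell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from . import cardio, neuro, respiratory
from .anatomy import effectors_below_lesion
from .config import ModelConfig
from .pathologies import PathologyPreset, apply_preset
from .patients import PatientProfile
from .state import PhysioState, _refresh_cardio_neuro, initial_state

#: Exported timeline columns: time, six clinical parameters, six
#: physiological parameters.
TIMELINE_COLUMNS = [
    "t",
    "spo2", "rr", "hr", "map", "gcs", "walks",
    "alveolar_volume", "pao2", "paco2", "blood_volume", "stroke_volume", "icp",
]

#: Duration of the pre-insult settling run used to start every simulation
#: at the model's own healthy equilibrium (longer than 5 lag constants).
SETTLE_SECONDS = 600.0


class EngineFault(RuntimeError):
    """A state variable left the representable domain (NaN/inf)."""


def step(
    state: PhysioState,
    profile: PatientProfile,
    presets: Sequence[PathologyPreset],
    config: ModelConfig,
    dt: float,
) -> PhysioState:
    """Advance the state by one time step of ``dt`` seconds."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    cfg = config
    s = state.copy()
    s.t = state.t + dt

    # (1) pathology mutators write into the new state's accumulators; all
    # later sub-updates read the *previous* state's accumulators, so a
    # mutation becomes visible to the physiology one step later and the
    # update order within a step is immaterial.
    for preset in presets:
        apply_preset(s, preset, profile, cfg, dt)

    # (2) respiratory chain
    eff = effectors_below_lesion(state.lesion)
    vt_baseline = cfg.resp.vt_per_kg_ibw * profile.ideal_weight
    s.rr, s.tidal_volume = respiratory.respiratory_drive(
        state.paco2, state.pao2,
        eff.diaphragm_intact, state.airway_patency, eff.intercostals_intact,
        vt_baseline, state.vt_ceiling, cfg.resp,
    )
    s.alveolar_volume = (
        max(0.0, s.tidal_volume - profile.dead_space) * state.functional_fraction
    )
    s.va = s.rr * s.alveolar_volume / 1000.0
    gas = respiratory.arterial_gases(
        s.va, s.vo2, state.pao2, state.paco2, state.o2_store,
        s.o2_store_capacity, dt, cfg.resp,
    )
    s.pao2, s.paco2, s.o2_store = gas.pao2, gas.paco2, gas.o2_store
    s.spo2 = respiratory.spo2_from_pao2(s.pao2)

    # (3) sympathetic drive (reads previous-step MAP and gases)
    s.sympathetic = cardio.sympathetic_drive(
        state.sympathetic, state.map_eff, state.pao2, state.paco2, dt, cfg.cardio
    )

    # (4) cardiovascular chain + (5) neurological outputs
    _refresh_cardio_neuro(
        s, profile, cfg,
        blood_volume=state.blood_volume,
        pericardial_volume=state.pericardial_volume,
        pleural_pressure=state.pleural_pressure,
        bleed_volume=state.intracranial_bleed_volume,
    )
    s.walks = neuro.can_walk(s.gcs, eff, s.lower_limbs_intact, cfg.neuro)

    probe = s.map_eff + s.spo2 + s.cpp + s.blood_volume + s.icp + s.pao2
    if not math.isfinite(probe):
        bad = [
            name for name in ("map_eff", "spo2", "cpp", "blood_volume", "icp", "pao2")
            if not math.isfinite(getattr(s, name))
        ]
        raise EngineFault(f"non-finite state field(s) {bad} at t={s.t}")
    return s


def _is_fatal(state: PhysioState, config: ModelConfig) -> bool:
    d = config.engine.death
    return (
        state.cpp < d.cpp_min
        or state.spo2 < d.spo2_min
        or state.co_eff < d.co_eff_min
    )


def _timeline_row(state: PhysioState) -> tuple:
    return (
        state.t, state.spo2, state.rr, state.hr, state.map_eff, state.gcs,
        state.walks, state.alveolar_volume, state.pao2, state.paco2,
        state.blood_volume, state.sv, state.icp,
    )


@dataclass
class SimResult:
    timeline: pd.DataFrame
    time_of_death: Optional[float]
    final_state: PhysioState

    @property
    def survived(self) -> bool:
        return self.time_of_death is None


def settle(
    profile: PatientProfile,
    config: ModelConfig,
    seconds: float = SETTLE_SECONDS,
) -> PhysioState:
    """Run the healthy model to its equilibrium (the pre-insult T0 state)."""
    s = initial_state(profile, config)
    dt = config.engine.dt
    n = int(round(seconds / dt))
    for _ in range(n):
        s = step(s, profile, (), config, dt)
    s.t = 0.0
    return s


def run_until_death(
    profile: PatientProfile,
    presets: Sequence[PathologyPreset] | PathologyPreset,
    config: Optional[ModelConfig] = None,
    collect_timeline: bool = True,
) -> SimResult:
    """Integrate an untreated scenario to death or the horizon.

    The patient starts at the settled healthy equilibrium; presets act from
    their onset times.  The timeline is sampled every ``export_stride``
    seconds (plus the final step); the time of death, when reached, is
    reported at ``dt`` resolution as the first entry into the fatal dwell.
    """
    cfg = config or ModelConfig()
    if isinstance(presets, PathologyPreset):
        presets = (presets,)
    dt = cfg.engine.dt
    stride_steps = max(1, int(round(cfg.engine.export_stride / dt)))
    n_steps = int(round(cfg.engine.horizon / dt))

    s = settle(profile, cfg)
    rows = [_timeline_row(s)] if collect_timeline else []
    fatal_since: Optional[float] = None
    time_of_death: Optional[float] = None

    for i in range(1, n_steps + 1):
        s = step(s, profile, presets, cfg, dt)
        if collect_timeline and (i % stride_steps == 0 or i == n_steps):
            rows.append(_timeline_row(s))
        if _is_fatal(s, cfg):
            if fatal_since is None:
                fatal_since = s.t
            elif s.t - fatal_since >= cfg.engine.death.dwell:
                time_of_death = fatal_since
                break
        else:
            fatal_since = None

    if collect_timeline:
        if time_of_death is not None and rows[-1][0] != s.t:
            rows.append(_timeline_row(s))
        timeline = pd.DataFrame(rows, columns=TIMELINE_COLUMNS)
    else:
        timeline = pd.DataFrame(columns=TIMELINE_COLUMNS)
    return SimResult(timeline=timeline, time_of_death=time_of_death, final_state=s)


def _hms(seconds: float) -> str:
    seconds = int(round(seconds))
    h, rem = divmod(seconds, 3600)
    m, sec = divmod(rem, 60)
    return f"{h}:{m:02d}:{sec:02d}"


def sample_t0_t4(
    timeline: pd.DataFrame,
    time_of_death: Optional[float],
    horizon: float = 14400.0,
) -> pd.DataFrame:
    """The five-point assessment sampling of a timeline.

    T4 is the time of death (capped at the horizon, and equal to it for
    survivors); T1-T3 fall at 25/50/75 % of T4 and T0 is the pre-insult
    state.  Rows are the nearest exported samples, tagged with the label
    and the absolute time as h:mm:ss.
    """
    if timeline.empty:
        raise ValueError("timeline is empty")
    t4 = min(time_of_death, horizon) if time_of_death is not None else horizon
    targets = [0.0, 0.25 * t4, 0.5 * t4, 0.75 * t4, t4]
    out = []
    times = timeline["t"].to_numpy()
    for label, target in zip(["T0", "T1", "T2", "T3", "T4"], targets):
        idx = int(abs(times - target).argmin())
        row = timeline.iloc[idx].to_dict()
        row["label"] = label
        row["target_t"] = target
        row["clock"] = _hms(target)
        out.append(row)
    df = pd.DataFrame(out)
    return df[["label", "target_t", "clock"] + TIMELINE_COLUMNS]
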
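"""The three-rule cellular automaton.

Each "cell" is a region of the uterine wall — the patch one propagating
action potential can fully recruit — not an individual myocyte.  Per step:

1. **Pressure** (hydraulic coupling): intrauterine pressure is the mean of
   regional contractile activities referred back through each region's
   anatomy factor, floored at the baseline (minimum) pressure::

       pressure = max(min_pressure, mean(activity(i,j) / anatomy(i,j)))

2. **Passive tension** (Law of Laplace): each region feels
   ``pressure * anatomy(i,j)``.

3. **Burst/refractory modulation**: a quiescent region whose passive
   tension exceeds its action-potential threshold starts a burst; while
   bursting its activity is the passive tension times the AP multiplier
   (> 1), for at most ``burst_duration`` steps or until the amplified
   tension falls below threshold; it then spends ``refractory_duration``
   steps with activity damped by the refractory multiplier (< 1) before
   returning to quiescence.

Activity saturates at ``activity_cap`` (display scale 0-10; a region at
the cap is fully contracted).  Phase decisions are made from the tension
implied by the *previous* step's pressure, then activities and the new
pressure are computed — this ordering resolves the mutual dependence of
burst state and activity and makes the update a pure function of state.

One time step corresponds to roughly 5 s of wall-clock labor (a burst of
10-12 steps matches the 50-60 s electrical bursts recorded in human
myometrial strips); the engine itself is unitless in time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from typing import Optional

import numpy as np

from .config import SimulationConfig, config_to_mapping, validate_config
from .fields import RegionFields, build_fields

__all__ = [
    "RegionPhase",
    "EngineState",
    "SimulationResult",
    "initial_state",
    "compute_pressure",
    "update_phases",
    "step",
    "run",
    "save_trace_csv",
    "save_activity_csv",
    "save_run_metadata",
]


class RegionPhase(IntEnum):
    """Electrical phase of a region.

    Legal transitions: QUIESCENT -> BURSTING -> REFRACTORY -> QUIESCENT.
    A region leaving refractoriness is quiescent for at least one step
    before it can re-burst.
    """

    QUIESCENT = 0
    BURSTING = 1
    REFRACTORY = 2


@dataclass(frozen=True)
class EngineState:
    """Full per-step state: time, activity grid, pressure, phase machine."""

    t: int
    activity: np.ndarray      # rows x columns, non-negative, <= activity_cap
    pressure: float
    phase: np.ndarray         # rows x columns, RegionPhase codes
    phase_age: np.ndarray     # steps spent in the current phase


@dataclass(frozen=True)
class SimulationResult:
    """Recorded run: pressure trace plus activity and phase tensors.

    ``pressure_trace`` has length ``timesteps + 1`` (index 0 is the initial
    state); the tensors have shape ``(timesteps + 1, rows, columns)``.
    """

    pressure_trace: np.ndarray
    activity_tensor: np.ndarray
    phase_tensor: np.ndarray
    config: SimulationConfig
    fields: RegionFields

    @property
    def timesteps(self) -> int:
        return len(self.pressure_trace) - 1


def compute_pressure(
    activity: np.ndarray, fields: RegionFields, cfg: SimulationConfig
) -> float:
    """Rule 1: organ pressure from regional activities, floored at baseline."""
    raw = float(np.mean(np.asarray(activity) / fields.anatomy))
    return max(cfg.min_pressure, raw)


def initial_state(cfg: SimulationConfig, fields: RegionFields) -> EngineState:
    """All regions quiescent; activities set by the starting pressure."""
    if fields.shape != (cfg.rows, cfg.columns):
        raise ValueError(
            f"fields shape {fields.shape} does not match configured grid "
            f"{(cfg.rows, cfg.columns)}"
        )
    activity = np.clip(cfg.initial_pressure * fields.anatomy, 0.0, cfg.activity_cap)
    pressure = compute_pressure(activity, fields, cfg)
    shape = (cfg.rows, cfg.columns)
    return EngineState(
        t=0,
        activity=activity,
        pressure=pressure,
        phase=np.full(shape, RegionPhase.QUIESCENT, dtype=np.int8),
        phase_age=np.zeros(shape, dtype=np.int64),
    )


def update_phases(
    state: EngineState,
    passive: np.ndarray,
    cfg: SimulationConfig,
    fields: RegionFields,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the per-region phase machine given the passive tensions.

    Initiation compares the passive tension to the threshold strictly
    (equality does not fire); continuation of a burst requires the
    amplified tension ``passive * ap_multiplier`` to stay at or above
    threshold and the burst age to stay within ``burst_duration``.
    """
    phase = state.phase
    age = state.phase_age
    thr = fields.threshold

    new_phase = phase.copy()
    new_age = age + 1

    quiescent = phase == RegionPhase.QUIESCENT
    bursting = phase == RegionPhase.BURSTING
    refractory = phase == RegionPhase.REFRACTORY

    ignite = quiescent & (passive > thr)
    new_phase[ignite] = RegionPhase.BURSTING
    new_age[ignite] = 1

    burst_over = bursting & (
        (age + 1 > cfg.burst_duration) | (passive * cfg.ap_multiplier < thr)
    )
    new_phase[burst_over] = RegionPhase.REFRACTORY
    new_age[burst_over] = 1

    refr_over = refractory & (age + 1 > cfg.refractory_duration)
    new_phase[refr_over] = RegionPhase.QUIESCENT
    new_age[refr_over] = 0

    return new_phase, new_age


def step(
    state: EngineState, cfg: SimulationConfig, fields: RegionFields
) -> EngineState:
    """One synchronous update of all regions (Rules 2, 3, then 1)."""
    passive = state.pressure * fields.anatomy
    phase, age = update_phases(state, passive, cfg, fields)
    factor = np.ones_like(passive)
    factor[phase == RegionPhase.BURSTING] = cfg.ap_multiplier
    factor[phase == RegionPhase.REFRACTORY] = cfg.refractory_multiplier
    activity = np.clip(passive * factor, 0.0, cfg.activity_cap)
    pressure = compute_pressure(activity, fields, cfg)
    return EngineState(
        t=state.t + 1,
        activity=activity,
        pressure=pressure,
        phase=phase,
        phase_age=age,
    )


def run(
    cfg: SimulationConfig, fields: Optional[RegionFields] = None
) -> SimulationResult:
    """Run the automaton for ``cfg.timesteps`` steps and record everything.

    Deterministic: identical ``(cfg, fields)`` give bit-identical results.
    Fields are sampled from the configured Weibulls/seeds when not given.
    """
    validate_config(cfg)
    if fields is None:
        fields = build_fields(cfg)
    state = initial_state(cfg, fields)

    n = cfg.timesteps
    trace = np.empty(n + 1, dtype=float)
    act = np.empty((n + 1, cfg.rows, cfg.columns), dtype=float)
    pha = np.empty((n + 1, cfg.rows, cfg.columns), dtype=np.int8)
    trace[0] = state.pressure
    act[0] = state.activity
    pha[0] = state.phase
    for k in range(1, n + 1):
        state = step(state, cfg, fields)
        trace[k] = state.pressure
        act[k] = state.activity
        pha[k] = state.phase
    return SimulationResult(
        pressure_trace=trace,
        activity_tensor=act,
        phase_tensor=pha,
        config=cfg,
        fields=fields,
    )


# --------------------------------------------------------------------------
# Exports
# --------------------------------------------------------------------------

def save_trace_csv(result: SimulationResult, path) -> None:
    """Write the pressure trace as (step, pressure) CSV."""
    with open(path, "w") as fh:
        fh.write("step,pressure\n")
        for t, p in enumerate(result.pressure_trace):
            fh.write(f"{t},{p:.10g}\n")


def save_activity_csv(result: SimulationResult, path) -> None:
    """Write the activity/phase tensors long-form: step,row,col,activity,phase."""
    rows, cols = result.fields.shape
    with open(path, "w") as fh:
        fh.write("step,row,col,activity,phase\n")
        for t in range(len(result.pressure_trace)):
            for i in range(rows):
                for j in range(cols):
                    fh.write(
                        f"{t},{i},{j},{result.activity_tensor[t, i, j]:.10g},"
                        f"{int(result.phase_tensor[t, i, j])}\n"
                    )


def save_run_metadata(result: SimulationResult, path) -> None:
    """Write config, field provenance, and engine semantics alongside exports."""
    meta = {
        "config": config_to_mapping(result.config),
        "fields_provenance": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in result.fields.provenance.items()
        },
        "semantics": {
            "phase_order": "quiescent -> bursting -> refractory -> quiescent",
            "initiation": "passive tension strictly above threshold",
            "continuation": "amplified tension (passive * ap_multiplier) "
                            "at or above threshold, within burst_duration",
            "refractory_exit": "one quiescent step before re-initiation",
            "pressure_floor": "applied to organ pressure after Rule 1",
            "activity_cap": result.config.activity_cap,
            "step_seconds_approx": 5,
        },
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
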
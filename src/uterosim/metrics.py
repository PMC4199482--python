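"""Trace analysis: contraction detection, pseudo-Montevideo units,
pacemaker identification, and behavior classification.

The clinical Montevideo unit multiplies contraction amplitude above
baseline by contraction count per 10 minutes.  Its simulation analog here
(pMV) multiplies mean per-contraction peak pressure by the number of
contractions per 300-step window.

Behavior classes follow the Wolfram-style four-class scheme applied to
*input-value sets* rather than rules: 1 uniform, 2 repetitive, 3 chaotic,
4 complex/emergent.  The optional N/X/P physiological-relevance modifier
is an annotation supplied by the caller, never computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .engine import RegionPhase, SimulationResult

__all__ = [
    "ContractionEvent",
    "BehaviorClass",
    "PacemakerReport",
    "detect_contractions",
    "pseudo_montevideo",
    "pmv_from_events",
    "identify_pacemaker",
    "classify_behavior",
    "metrics_report",
]


@dataclass(frozen=True)
class ContractionEvent:
    """One organ-level contraction detected in a pressure trace."""

    onset_step: int
    offset_step: int
    peak_step: int
    peak_pressure: float

    def __post_init__(self):
        if not self.onset_step <= self.peak_step <= self.offset_step:
            raise ValueError("event must satisfy onset <= peak <= offset")


@dataclass(frozen=True)
class BehaviorClass:
    """Input-based CA class (1-4) with an optional caller-asserted modifier."""

    class_id: int
    modifier: Optional[str] = None


@dataclass(frozen=True)
class PacemakerReport:
    """Per-event apparent pacemakers and the run-dominant region.

    ``per_event`` holds 0-based (row, col) indices, or ``None`` when no
    bursting region could be attributed to an event.  ``dominant`` is the
    region with the highest frequency of burst activity over the whole
    run — the model's operational definition of *the* pacemaker.
    """

    per_event: tuple
    dominant: Optional[tuple]


_FLAT_TOL = 1e-9


def detect_contractions(
    trace: Sequence[float],
    level_fraction: float = 0.5,
    transient_skip: int = 20,
    baseline: Optional[float] = None,
) -> list[ContractionEvent]:
    """Detect organ-level contractions by relative-level thresholding.

    After discarding the first ``transient_skip`` steps (initial-condition
    artifacts must not count as contractions), events are maximal
    contiguous runs where pressure is at or above
    ``baseline + level_fraction * (max - baseline)``, with the maximum
    taken over the post-transient trace and the baseline defaulting to the
    post-transient minimum (normally the configured pressure floor).
    Because the level is relative, the event list is invariant under
    uniform rescaling of the trace.  A flat trace yields no events.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) <= transient_skip:
        raise ValueError(
            f"trace of length {len(trace)} is not longer than the "
            f"transient window ({transient_skip})"
        )
    if not 0 < level_fraction < 1:
        raise ValueError(f"level_fraction must be in (0,1), got {level_fraction}")
    seg = trace[transient_skip:]
    lo = float(np.min(seg)) if baseline is None else float(baseline)
    hi = float(np.max(seg))
    if hi - lo < _FLAT_TOL:
        return []
    level = lo + level_fraction * (hi - lo)
    above = seg >= level
    events: list[ContractionEvent] = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):  # [start, stop) above level
        window = seg[start:stop]
        peak_rel = int(start) + int(np.argmax(window))
        events.append(
            ContractionEvent(
                onset_step=transient_skip + int(start),
                offset_step=transient_skip + int(stop) - 1,
                peak_step=transient_skip + peak_rel,
                peak_pressure=float(seg[peak_rel]),
            )
        )
    return events


def pmv_from_events(
    events: Sequence[ContractionEvent], n_steps: int, window: int = 300
) -> float:
    """pMV = mean per-event peak pressure x contraction count per window.

    The count is rescaled to the standard 300-step window when the trace
    covers a different span.  Returns 0 when there are no events.
    """
    if not events:
        return 0.0
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    peaks = [e.peak_pressure for e in events]
    return float(np.mean(peaks)) * len(events) * (window / n_steps)


def pseudo_montevideo(
    trace: Sequence[float],
    window: int = 300,
    level_fraction: float = 0.5,
    transient_skip: int = 20,
) -> float:
    """Pseudo-Montevideo units of a pressure trace (see :func:`pmv_from_events`)."""
    trace = np.asarray(trace, dtype=float)
    events = detect_contractions(
        trace, level_fraction=level_fraction, transient_skip=transient_skip
    )
    return pmv_from_events(events, n_steps=len(trace) - 1, window=window)


def identify_pacemaker(
    result: SimulationResult, events: Sequence[ContractionEvent]
) -> PacemakerReport:
    """Attribute each contraction to the region whose burst triggered it.

    For each event the apparent pacemaker is the first region to enter the
    bursting phase in the window after the previous event's offset (and up
    to the event's peak) whose burst persists into the event's rising
    phase.  Ties at the same step resolve row-major.  The dominant
    pacemaker is the region with the most burst onsets over the run
    (highest frequency of activity), with total bursting steps as the
    tie-break — it need not lead every contraction.
    """
    if not events:
        raise ValueError("events must be non-empty")
    phases = result.phase_tensor
    nsteps, rows, cols = phases.shape
    bursting = phases == RegionPhase.BURSTING
    onsets = bursting.copy()
    onsets[1:] &= ~bursting[:-1]  # True where a burst begins

    per_event: list[Optional[tuple[int, int]]] = []
    prev_offset = 0
    for ev in events:
        start = prev_offset + 1
        stop = min(ev.peak_step, nsteps - 1)
        found: Optional[tuple[int, int]] = None
        for t in range(start, stop + 1):
            if not onsets[t].any():
                continue
            for i in range(rows):
                for j in range(cols):
                    if not onsets[t, i, j]:
                        continue
                    # burst must persist into the rising phase of the event
                    end = t
                    while end + 1 < nsteps and bursting[end + 1, i, j]:
                        end += 1
                    if end >= ev.onset_step:
                        found = (i, j)
                        break
                if found:
                    break
            if found:
                break
        per_event.append(found)
        prev_offset = ev.offset_step

    onset_counts = onsets.sum(axis=0)
    burst_steps = bursting.sum(axis=0)
    if burst_steps.max() == 0:
        dominant = None
    else:
        order = onset_counts * (nsteps + 1) + burst_steps  # lexicographic
        dominant = tuple(int(v) for v in np.unravel_index(np.argmax(order), (rows, cols)))
    return PacemakerReport(per_event=tuple(per_event), dominant=dominant)


def classify_behavior(
    trace: Sequence[float],
    events: Optional[Sequence[ContractionEvent]] = None,
    transient_skip: int = 20,
    cv_threshold: float = 0.05,
    variance_eps: float = 1e-9,
) -> BehaviorClass:
    """Assign an input-based CA class to a run.

    Class 1: the post-transient trace is uniform (variance below
    *variance_eps*, no contractions).  Class 2: at least three
    contractions with inter-onset intervals repeating to within a
    coefficient of variation below *cv_threshold*.  Class 4: at least
    three contractions whose intervals vary more than that (complex,
    emergent timing).  Class 3 is the fallback for sustained non-repeating
    fluctuation without organized contractions.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) <= transient_skip:
        raise ValueError(
            f"trace of length {len(trace)} is too short to classify "
            f"(transient window {transient_skip})"
        )
    if events is None:
        events = detect_contractions(trace, transient_skip=transient_skip)
    seg = trace[transient_skip:]
    if not events and float(np.var(seg)) < variance_eps:
        return BehaviorClass(1)
    if len(events) >= 3:
        onsets = np.array([e.onset_step for e in events], dtype=float)
        intervals = np.diff(onsets)
        cv = float(np.std(intervals) / np.mean(intervals))
        return BehaviorClass(2 if cv < cv_threshold else 4)
    return BehaviorClass(3)


def metrics_report(
    result: SimulationResult,
    level_fraction: float = 0.5,
    transient_skip: int = 20,
) -> dict:
    """Full JSON-ready metrics bundle for one run."""
    from .fields import mean_total_sensitivity

    trace = result.pressure_trace
    events = detect_contractions(
        trace, level_fraction=level_fraction, transient_skip=transient_skip
    )
    pmv = pmv_from_events(events, n_steps=len(trace) - 1)
    cls = classify_behavior(trace, events, transient_skip=transient_skip)
    if events:
        pace = identify_pacemaker(result, events)
        per_event = [list(p) if p is not None else None for p in pace.per_event]
        dominant = list(pace.dominant) if pace.dominant is not None else None
    else:
        per_event, dominant = [], None
    return {
        "events": [
            {
                "onset_step": e.onset_step,
                "offset_step": e.offset_step,
                "peak_step": e.peak_step,
                "peak_pressure": e.peak_pressure,
            }
            for e in events
        ],
        "pMV": pmv,
        "mean_total_sensitivity": mean_total_sensitivity(result.fields),
        "pacemaker_per_event": per_event,
        "dominant_pacemaker": dominant,
        "behavior_class": cls.class_id,
    }
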
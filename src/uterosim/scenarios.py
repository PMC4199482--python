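"""Named in-silico experiments built on the engine and metrics.

* **Drug sweeps** vary the action-potential multiplier with the
  heterogeneity fields held fixed: lowering it emulates a tocolytic
  (nifedipine, an L-type calcium-channel blocker), raising it a
  uterotonic (oxytocin).
* **Region sweeps** vary the grid size at fixed rule parameters; since
  region size is set by the action-potential propagation distance, this
  emulates changing tissue-level electrical connectivity.  Fields are
  resampled for every grid (the matrix shape changes), so per-run mean
  total sensitivity is reported alongside pMV.
* **Two-tissue runs** emulate two myometrial strips linked end-to-end in
  an isometric bath (a 1x2 grid with explicit tissue values), reporting a
  phase-coupling statistic: the fraction of steps with both regions
  bursting simultaneously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig, format_descriptor, validate_config
from .engine import RegionPhase, SimulationResult, run
from .fields import (
    RegionFields,
    build_fields,
    fields_from_matrices,
    mean_total_sensitivity,
)
from .metrics import (
    classify_behavior,
    detect_contractions,
    pmv_from_events,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SweepSpec",
    "TwoTissueSummary",
    "TWO_TISSUE_ANATOMY",
    "TWO_TISSUE_THRESHOLDS",
    "SINGLE_TISSUE_ANATOMY",
    "SINGLE_TISSUE_THRESHOLD",
    "two_tissue_fixture",
    "single_tissue_fixture",
    "has_coordinated_contractions",
    "scenario_drug_sweep",
    "scenario_region_sweep",
    "scenario_two_tissue",
    "default_region_grids",
]

# Published bench-top tissue values used as explicit fixtures: two strips
# with near-unity anatomy factors and asymmetric thresholds straddling the
# 0.5 pressure floor, and a single strip with anatomy ~1, threshold 0.558.
TWO_TISSUE_ANATOMY = (0.986, 0.989)
TWO_TISSUE_THRESHOLDS = (0.428, 0.670)
SINGLE_TISSUE_ANATOMY = 0.991
SINGLE_TISSUE_THRESHOLD = 0.558


def two_tissue_fixture() -> RegionFields:
    """1x2 fixture for the linked-strip isometric experiment."""
    return fields_from_matrices(
        [TWO_TISSUE_ANATOMY], [TWO_TISSUE_THRESHOLDS], note="two-tissue bench fixture"
    )


def single_tissue_fixture() -> RegionFields:
    """1x1 fixture for the isolated-strip experiment."""
    return fields_from_matrices(
        [[SINGLE_TISSUE_ANATOMY]],
        [[SINGLE_TISSUE_THRESHOLD]],
        note="single-tissue bench fixture",
    )


@dataclass(frozen=True)
class SweepSpec:
    """A one-variable sweep over a base configuration."""

    variable: str
    values: tuple
    base: SimulationConfig
    replicate_seeds: Optional[tuple] = None

    _ALLOWED = (
        "ap_multiplier",
        "n_regions",
        "min_pressure",
        "initial_pressure",
        "refractory_duration",
    )

    def __post_init__(self):
        if self.variable not in self._ALLOWED:
            raise ValueError(
                f"sweep variable must be one of {self._ALLOWED}, got {self.variable!r}"
            )
        if not self.values:
            raise ValueError("sweep values must be non-empty")


def has_coordinated_contractions(
    trace: Sequence[float],
    min_events: int = 3,
    min_peak: float = 5.0,
    transient_skip: int = 20,
) -> bool:
    """Operational test for organ-level coordination.

    True when the trace contains at least *min_events* contractions whose
    mean peak pressure reaches *min_peak* (half the activity cap by
    default) — i.e. repeated recruitment of most regions, as opposed to
    small localized oscillations.
    """
    events = detect_contractions(trace, transient_skip=transient_skip)
    if len(events) < min_events:
        return False
    return float(np.mean([e.peak_pressure for e in events])) >= min_peak


def _run_metrics_row(result: SimulationResult) -> dict:
    trace = result.pressure_trace
    events = detect_contractions(trace)
    return {
        "pmv": pmv_from_events(events, n_steps=len(trace) - 1),
        "n_events": len(events),
        "peak_pressure": float(np.max(trace[20:])),
        "behavior_class": classify_behavior(trace, events).class_id,
        "coordinated": has_coordinated_contractions(trace),
    }


def scenario_drug_sweep(
    base: SimulationConfig,
    multipliers: Sequence[float],
    fields: Optional[RegionFields] = None,
) -> pd.DataFrame:
    """Run one simulation per AP multiplier with fields held fixed.

    Holding the heterogeneity matrices constant across the sweep isolates
    the drug effect: the same "patient" at different doses.
    """
    validate_config(base)
    if fields is None:
        fields = build_fields(base)
    logger.info("drug sweep over %s on %s", list(multipliers), format_descriptor(base))
    rows = []
    for m in multipliers:
        cfg = base.replace(ap_multiplier=float(m))
        result = run(cfg, fields)
        rows.append({"ap_multiplier": float(m), **_run_metrics_row(result)})
    return pd.DataFrame(rows)


def default_region_grids() -> list[tuple[int, int]]:
    """Near-square factorizations spanning 4 to 64 regions."""
    return [
        (2, 2), (2, 3), (3, 3), (3, 4), (4, 4), (6, 3), (4, 5), (5, 5),
        (5, 6), (4, 8), (6, 6), (6, 7), (7, 7), (7, 8), (8, 8),
    ]


def scenario_region_sweep(
    base: SimulationConfig,
    grids: Optional[Sequence[tuple[int, int]]] = None,
) -> pd.DataFrame:
    """Run one simulation per grid shape, resampling fields each time.

    Changing the region count changes the matrix shapes, so each grid gets
    freshly sampled heterogeneity fields from the configured seeds; the
    per-run mean total sensitivity is reported so that force trends can be
    separated from sampling drift.
    """
    if grids is None:
        grids = default_region_grids()
    rows = []
    for r, c in grids:
        cfg = base.replace(rows=int(r), columns=int(c))
        validate_config(cfg)
        flds = build_fields(cfg)
        result = run(cfg, flds)
        rows.append(
            {
                "rows": int(r),
                "columns": int(c),
                "n_regions": int(r) * int(c),
                "mean_total_sensitivity": mean_total_sensitivity(flds),
                **_run_metrics_row(result),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TwoTissueSummary:
    """Result of a linked-strip run plus its phase-relation statistics."""

    result: SimulationResult
    burst_onsets: tuple          # per-region tuples of burst onset steps
    burst_intervals: tuple       # per-region tuples of inter-onset intervals
    overlap_fraction: float      # fraction of steps with both regions bursting

    @property
    def in_phase(self) -> bool:
        """Heuristic: coupled when regions co-burst for >10% of steps."""
        return self.overlap_fraction > 0.10


def scenario_two_tissue(
    fixture: RegionFields, base: SimulationConfig
) -> TwoTissueSummary:
    """Run the two-strip experiment and summarize phase coupling."""
    if fixture.shape != (1, 2):
        raise ValueError(f"two-tissue fixture must be 1x2, got {fixture.shape}")
    cfg = base.replace(rows=1, columns=2)
    result = run(cfg, fixture)
    phases = result.phase_tensor[:, 0, :]  # (steps, 2)
    bursting = phases == RegionPhase.BURSTING
    onsets_per_region = []
    intervals_per_region = []
    for j in range(2):
        b = bursting[:, j].astype(np.int8)
        on = np.flatnonzero(np.diff(np.concatenate(([0], b))) == 1)
        onsets_per_region.append(tuple(int(t) for t in on))
        intervals_per_region.append(tuple(int(d) for d in np.diff(on)))
    overlap = float(np.mean(bursting[:, 0] & bursting[:, 1]))
    return TwoTissueSummary(
        result=result,
        burst_onsets=tuple(onsets_per_region),
        burst_intervals=tuple(intervals_per_region),
        overlap_fraction=overlap,
    )
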
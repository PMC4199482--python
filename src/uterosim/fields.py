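"""Per-region heterogeneity fields.

Two matrices describe the regions of the uterine wall and stay fixed for
the duration of a run:

* **anatomy sensitivity** — the Law-of-Laplace r/w factor converting organ
  pressure to regional passive tension (and back);
* **action-potential threshold** — the tension above which a region fires
  a burst.

Both are sampled once per run from three-parameter Weibull distributions
with separate seeds, or injected explicitly (e.g. to reproduce a bench-top
fixture with known tissue values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import SimulationConfig, WeibullSpec

__all__ = [
    "RegionFields",
    "sample_weibull_matrix",
    "build_fields",
    "fields_from_matrices",
    "load_matrix_csv",
    "save_matrix_csv",
    "load_fields",
    "total_sensitivity",
    "mean_total_sensitivity",
    "nominal_pacemaker",
]


@dataclass(frozen=True)
class RegionFields:
    """Paired anatomy-sensitivity and threshold matrices for one run."""

    anatomy: np.ndarray
    threshold: np.ndarray
    provenance: dict

    def __post_init__(self):
        a = np.asarray(self.anatomy, dtype=float)
        t = np.asarray(self.threshold, dtype=float)
        if a.ndim != 2 or t.ndim != 2:
            raise ValueError("region matrices must be 2-D")
        if a.shape != t.shape:
            raise ValueError(
                f"anatomy {a.shape} and threshold {t.shape} shapes differ"
            )
        if not np.all(a > 0):
            raise ValueError("anatomy sensitivities must be positive")
        if not np.all(t > 0):
            raise ValueError("action-potential thresholds must be positive")
        a.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "anatomy", a)
        object.__setattr__(self, "threshold", t)

    @property
    def shape(self) -> tuple[int, int]:
        return self.anatomy.shape


def sample_weibull_matrix(
    spec: WeibullSpec, rows: int, columns: int, seed: int
) -> np.ndarray:
    """Draw a rows x columns matrix of ``location + scale * Weibull(shape)``.

    The matrix is filled row-major from a generator seeded with *seed*, so
    identical ``(spec, shape, seed)`` always reproduce the same matrix.
    """
    if rows < 1 or columns < 1:
        raise ValueError(f"grid must be at least 1x1, got {rows}x{columns}")
    rng = np.random.default_rng(seed)
    draws = spec.location + spec.scale * rng.weibull(spec.shape, size=rows * columns)
    return draws.reshape(rows, columns)


def build_fields(cfg: SimulationConfig) -> RegionFields:
    """Sample both heterogeneity matrices for *cfg* (independent seeds)."""
    anatomy = sample_weibull_matrix(
        cfg.anatomy_weibull, cfg.rows, cfg.columns, cfg.anatomy_seed
    )
    threshold = sample_weibull_matrix(
        cfg.threshold_weibull, cfg.rows, cfg.columns, cfg.threshold_seed
    )
    return RegionFields(
        anatomy=anatomy,
        threshold=threshold,
        provenance={
            "kind": "sampled",
            "anatomy_seed": cfg.anatomy_seed,
            "threshold_seed": cfg.threshold_seed,
            "anatomy_weibull": (
                cfg.anatomy_weibull.shape,
                cfg.anatomy_weibull.scale,
                cfg.anatomy_weibull.location,
            ),
            "threshold_weibull": (
                cfg.threshold_weibull.shape,
                cfg.threshold_weibull.scale,
                cfg.threshold_weibull.location,
            ),
        },
    )


def fields_from_matrices(anatomy, threshold, note: str = "explicit") -> RegionFields:
    """Wrap explicit matrices (e.g. published bench-top tissue values)."""
    return RegionFields(
        anatomy=np.atleast_2d(np.asarray(anatomy, dtype=float)),
        threshold=np.atleast_2d(np.asarray(threshold, dtype=float)),
        provenance={"kind": "fixture", "note": note},
    )


def load_matrix_csv(path) -> np.ndarray:
    """Load a region matrix from CSV, one grid row per line."""
    m = np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float))
    return m


def save_matrix_csv(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.atleast_2d(matrix), delimiter=",", fmt="%.17g")


def load_fields(anatomy_path, threshold_path) -> RegionFields:
    """Load both matrices from CSV fixture files."""
    return RegionFields(
        anatomy=load_matrix_csv(anatomy_path),
        threshold=load_matrix_csv(threshold_path),
        provenance={
            "kind": "fixture",
            "anatomy_file": str(anatomy_path),
            "threshold_file": str(threshold_path),
        },
    )


def total_sensitivity(fields: RegionFields) -> np.ndarray:
    """Elementwise anatomy sensitivity / action-potential threshold.

    A region is more easily recruited when its anatomy factor is high (more
    tension per unit pressure) or its threshold low, so this ratio ranks
    regions by pace-making propensity; its argmax is the nominal pacemaker.
    """
    return fields.anatomy / fields.threshold


def mean_total_sensitivity(fields: RegionFields) -> float:
    """Arithmetic mean of the total-sensitivity matrix."""
    return float(np.mean(total_sensitivity(fields)))


def nominal_pacemaker(fields: RegionFields) -> tuple[int, int]:
    """0-based (row, column) of the region with the highest total sensitivity."""
    ts = total_sensitivity(fields)
    idx = int(np.argmax(ts))
    return np.unravel_index(idx, ts.shape)  # type: ignore[return-value]
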
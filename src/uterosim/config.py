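"""Simulation configuration: input variables, presets, and descriptor strings.

The simulator takes a small set of scalar inputs (grid shape, pressures,
burst/refractory timing, amplification factors) plus two three-parameter
Weibull distributions that describe per-region heterogeneity of wall
anatomy (the Law-of-Laplace r/w factor) and of the action-potential
threshold.  Fourteen named preset input sets cover the bench-top and
whole-organ experiments; a compact descriptor string encodes a full
configuration on one line, e.g.::

    1.S1000:1.8/1/0.3; S2000:4/0.6/0.4

The prefix selects preset 1 (or spells out all nine scalars slash-separated),
``S1``/``S2`` carry the seeds for the anatomy-sensitivity and threshold
fields, and the two triples are the Weibull (shape, scale, location)
parameters of those fields.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping, Optional

import yaml

__all__ = [
    "WeibullSpec",
    "SimulationConfig",
    "InputSet",
    "ConfigError",
    "PresetError",
    "DescriptorError",
    "PlausibilityWarning",
    "SeedRangeWarning",
    "DEFAULT_ANATOMY_WEIBULL",
    "DEFAULT_THRESHOLD_WEIBULL",
    "MAX_REGIONS",
    "preset_input_set",
    "parse_descriptor",
    "format_descriptor",
    "validate_config",
    "default_config",
    "config_from_mapping",
    "config_to_mapping",
    "load_config",
    "save_config",
]

#: Upper bound on the number of regions the simulator accepts.
MAX_REGIONS = 64


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class PresetError(ConfigError):
    """Unknown preset input-set number."""


class DescriptorError(ConfigError):
    """Malformed configuration descriptor string."""


class PlausibilityWarning(UserWarning):
    """Configuration is legal but physiologically questionable."""


class SeedRangeWarning(UserWarning):
    """Seed falls outside the conventional bookkeeping range."""


@dataclass(frozen=True)
class WeibullSpec:
    """Three-parameter Weibull distribution: shape, scale, location.

    Support is ``[location, inf)``; draws are ``location + scale * W`` with
    ``W`` standard Weibull(shape).
    """

    shape: float
    scale: float
    location: float

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise ConfigError(f"Weibull shape must be > 0, got {self.shape}")
        if not self.scale > 0:
            raise ConfigError(f"Weibull scale must be > 0, got {self.scale}")
        if self.location < 0:
            raise ConfigError(
                f"Weibull location must be >= 0, got {self.location}"
            )

    @property
    def mean(self) -> float:
        """Analytic mean, location + scale * Gamma(1 + 1/shape)."""
        from math import gamma

        return self.location + self.scale * gamma(1.0 + 1.0 / self.shape)


#: Default anatomy-sensitivity distribution: skewed about 1, support >= 0.3.
DEFAULT_ANATOMY_WEIBULL = WeibullSpec(1.8, 1.0, 0.3)
#: Default action-potential-threshold distribution, support >= 0.4.
DEFAULT_THRESHOLD_WEIBULL = WeibullSpec(4.0, 0.6, 0.4)


@dataclass(frozen=True)
class SimulationConfig:
    """Complete input-variable set for one simulation run."""

    rows: int = 4
    columns: int = 4
    timesteps: int = 300
    initial_pressure: float = 0.5
    min_pressure: float = 0.5
    burst_duration: int = 10
    refractory_duration: int = 20
    ap_multiplier: float = 3.0
    refractory_multiplier: float = 0.2
    anatomy_weibull: WeibullSpec = DEFAULT_ANATOMY_WEIBULL
    threshold_weibull: WeibullSpec = DEFAULT_THRESHOLD_WEIBULL
    anatomy_seed: int = 1000
    threshold_seed: int = 2000
    #: Saturating bound on regional contractile activity (display scale 0-10).
    activity_cap: float = 10.0

    @property
    def n_regions(self) -> int:
        return self.rows * self.columns

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class InputSet:
    """One row of the preset table: the nine scalar inputs.

    ``rows``/``columns`` are ``None`` for the symbolic preset (set 14),
    which leaves the grid shape to the caller.
    """

    set_number: int
    rows: Optional[int]
    columns: Optional[int]
    timesteps: int
    initial_pressure: float
    min_pressure: float
    burst_duration: int
    refractory_duration: int
    ap_multiplier: float
    refractory_multiplier: float


# The fourteen published preset input sets.  Tuple order:
# rows, columns, timesteps, initial P, minimum P, burst, refractory,
# AP multiplier, refractory multiplier.
_PRESET_ROWS: dict[int, tuple] = {
    1: (4, 4, 300, 0.5, 0.5, 10, 20, 3.0, 0.2),
    2: (4, 4, 300, 0.5, 0.5, 10, 20, 2.0, 0.2),
    3: (4, 4, 300, 0.5, 0.5, 10, 20, 1.5, 0.2),
    4: (5, 5, 300, 0.5, 0.5, 8, 26, 1.5, 0.2),
    5: (5, 5, 300, 0.5, 0.5, 8, 26, 2.0, 0.2),
    6: (5, 5, 300, 0.5, 0.5, 8, 26, 4.0, 0.2),
    7: (5, 5, 300, 0.5, 0.5, 8, 26, 8.0, 0.2),
    8: (5, 5, 300, 0.5, 0.5, 10, 12, 3.0, 0.2),
    9: (1, 1, 300, 1.0, 0.6, 10, 20, 3.0, 0.2),
    10: (1, 1, 300, 1.0, 0.55, 10, 20, 3.0, 0.2),
    11: (1, 2, 300, 0.5, 0.5, 10, 14, 3.0, 0.1),
    12: (1, 2, 300, 1.0, 0.5, 10, 14, 3.0, 0.1),
    13: (1, 2, 300, 0.5, 0.5, 10, 10, 3.0, 0.1),
    14: (None, None, 300, 0.5, 0.5, 10, 20, 2.0, 0.2),
}


def preset_input_set(set_number: int) -> InputSet:
    """Return preset input set 1-14.

    Set 14 has symbolic rows/columns (``None``): the caller supplies the
    grid when building a full configuration from it.
    """
    try:
        row = _PRESET_ROWS[int(set_number)]
    except (KeyError, TypeError, ValueError):
        raise PresetError(
            f"preset input set must be an integer 1-14, got {set_number!r}"
        ) from None
    return InputSet(int(set_number), *row)


def _config_from_input_set(
    s: InputSet,
    rows: Optional[int] = None,
    columns: Optional[int] = None,
    **overrides,
) -> SimulationConfig:
    r = s.rows if s.rows is not None else rows
    c = s.columns if s.columns is not None else columns
    if r is None or c is None:
        raise ConfigError(
            f"input set {s.set_number} has symbolic grid shape; "
            "rows and columns must be supplied"
        )
    base = dict(
        rows=r,
        columns=c,
        timesteps=s.timesteps,
        initial_pressure=s.initial_pressure,
        min_pressure=s.min_pressure,
        burst_duration=s.burst_duration,
        refractory_duration=s.refractory_duration,
        ap_multiplier=s.ap_multiplier,
        refractory_multiplier=s.refractory_multiplier,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def default_config(
    set_number: int = 1,
    rows: Optional[int] = None,
    columns: Optional[int] = None,
    **overrides,
) -> SimulationConfig:
    """Build a full configuration from a preset, with optional overrides."""
    return _config_from_input_set(
        preset_input_set(set_number), rows=rows, columns=columns, **overrides
    )


# --------------------------------------------------------------------------
# Descriptor strings
# --------------------------------------------------------------------------

_DESCRIPTOR_RE = re.compile(
    r"""^\s*
    (?P<x>.+?)                     # preset number or nine slash-sep values
    \s*\.\s*S\s*(?P<s1>\d+)\s*:\s*
    (?P<w1>[^/;\s]+)\s*/\s*(?P<w2>[^/;\s]+)\s*/\s*(?P<w3>[^/;\s]+)
    \s*;\s*S\s*(?P<s2>\d+)\s*:\s*
    (?P<w4>[^/;\s]+)\s*/\s*(?P<w5>[^/;\s]+)\s*/\s*(?P<w6>[^/;\s]+)
    \s*$""",
    re.VERBOSE,
)


def _num(token: str, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise DescriptorError(f"cannot parse {what} from token {token!r}") from None


def _int_token(token: str, what: str) -> int:
    v = _num(token, what)
    if v != int(v):
        raise DescriptorError(f"{what} must be an integer, got {token!r}")
    return int(v)


def parse_descriptor(
    text: str,
    base: Optional[InputSet] = None,
    rows: Optional[int] = None,
    columns: Optional[int] = None,
) -> SimulationConfig:
    """Parse a one-line descriptor into a full :class:`SimulationConfig`.

    The prefix before ``.S1...`` is either a preset number (ignored when
    *base* is given) or the nine scalar inputs slash-separated in table
    order.  Seeds are taken literally from the digits after each ``S``;
    values outside the conventional ranges (1000-1999 for anatomy,
    2000-2999 for threshold) are accepted with a warning.
    """
    m = _DESCRIPTOR_RE.match(text)
    if m is None:
        raise DescriptorError(
            f"descriptor {text!r} does not match "
            "'<x>.S1yyy:w1/w2/w3;S2zzz:w4/w5/w6'"
        )
    anatomy_seed = int(m["s1"])
    threshold_seed = int(m["s2"])
    if not 1000 <= anatomy_seed <= 1999:
        warnings.warn(
            f"anatomy seed {anatomy_seed} outside conventional range 1000-1999",
            SeedRangeWarning,
            stacklevel=2,
        )
    if not 2000 <= threshold_seed <= 2999:
        warnings.warn(
            f"threshold seed {threshold_seed} outside conventional range 2000-2999",
            SeedRangeWarning,
            stacklevel=2,
        )
    anatomy_w = WeibullSpec(
        _num(m["w1"], "anatomy Weibull shape"),
        _num(m["w2"], "anatomy Weibull scale"),
        _num(m["w3"], "anatomy Weibull location"),
    )
    threshold_w = WeibullSpec(
        _num(m["w4"], "threshold Weibull shape"),
        _num(m["w5"], "threshold Weibull scale"),
        _num(m["w6"], "threshold Weibull location"),
    )

    x = m["x"].strip()
    common = dict(
        anatomy_weibull=anatomy_w,
        threshold_weibull=threshold_w,
        anatomy_seed=anatomy_seed,
        threshold_seed=threshold_seed,
    )
    if base is not None:
        return _config_from_input_set(base, rows=rows, columns=columns, **common)
    if "/" in x:
        parts = [p.strip() for p in x.split("/")]
        if len(parts) != 9:
            raise DescriptorError(
                f"long-form prefix must have 9 slash-separated values, "
                f"got {len(parts)} in {x!r}"
            )
        return SimulationConfig(
            rows=_int_token(parts[0], "rows"),
            columns=_int_token(parts[1], "columns"),
            timesteps=_int_token(parts[2], "timesteps"),
            initial_pressure=_num(parts[3], "initial pressure"),
            min_pressure=_num(parts[4], "minimum pressure"),
            burst_duration=_int_token(parts[5], "burst duration"),
            refractory_duration=_int_token(parts[6], "refractory duration"),
            ap_multiplier=_num(parts[7], "AP multiplier"),
            refractory_multiplier=_num(parts[8], "refractory multiplier"),
            **common,
        )
    set_number = _int_token(x, "preset number")
    return _config_from_input_set(
        preset_input_set(set_number), rows=rows, columns=columns, **common
    )


def _fmt(v: float) -> str:
    # shortest representation that round-trips exactly through float()
    s = repr(float(v))
    return s[:-2] if s.endswith(".0") else s


def format_descriptor(cfg: SimulationConfig) -> str:
    """Serialize a configuration to the long-form descriptor string."""
    scalars = "/".join(
        [
            str(cfg.rows),
            str(cfg.columns),
            str(cfg.timesteps),
            _fmt(cfg.initial_pressure),
            _fmt(cfg.min_pressure),
            str(cfg.burst_duration),
            str(cfg.refractory_duration),
            _fmt(cfg.ap_multiplier),
            _fmt(cfg.refractory_multiplier),
        ]
    )
    a, t = cfg.anatomy_weibull, cfg.threshold_weibull
    return (
        f"{scalars}.S{cfg.anatomy_seed}:"
        f"{_fmt(a.shape)}/{_fmt(a.scale)}/{_fmt(a.location)};"
        f"S{cfg.threshold_seed}:"
        f"{_fmt(t.shape)}/{_fmt(t.scale)}/{_fmt(t.location)}"
    )


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def validate_config(cfg: SimulationConfig) -> SimulationConfig:
    """Check type invariants and bounds; return *cfg* unchanged if valid.

    Raises :class:`ConfigError` on hard violations.  A minimum pressure far
    from 0.5 is legal but draws a :class:`PlausibilityWarning`: on the 0-10
    activity scale the laboring uterus keeps a baseline near 1/20 of peak
    pressure, so the floor should stay near 0.5.
    """
    if cfg.rows < 1 or cfg.columns < 1:
        raise ConfigError(f"grid must be at least 1x1, got {cfg.rows}x{cfg.columns}")
    n = cfg.n_regions
    if not 1 <= n <= MAX_REGIONS:
        raise ConfigError(
            f"number of regions must be 1-{MAX_REGIONS}, got {n} "
            f"({cfg.rows}x{cfg.columns})"
        )
    if cfg.timesteps < 1:
        raise ConfigError(f"timesteps must be >= 1, got {cfg.timesteps}")
    if cfg.burst_duration < 1:
        raise ConfigError(f"burst duration must be >= 1, got {cfg.burst_duration}")
    if cfg.refractory_duration < 0:
        raise ConfigError(
            f"refractory duration must be >= 0, got {cfg.refractory_duration}"
        )
    if cfg.initial_pressure < 0:
        raise ConfigError(
            f"initial pressure must be >= 0, got {cfg.initial_pressure}"
        )
    if cfg.min_pressure < 0:
        raise ConfigError(f"minimum pressure must be >= 0, got {cfg.min_pressure}")
    if not cfg.ap_multiplier > 1:
        raise ConfigError(
            f"AP multiplier must be > 1, got {cfg.ap_multiplier}"
        )
    if not 0 < cfg.refractory_multiplier < 1:
        raise ConfigError(
            "refractory multiplier must be in (0, 1), "
            f"got {cfg.refractory_multiplier}"
        )
    if not cfg.activity_cap > 0:
        raise ConfigError(f"activity cap must be > 0, got {cfg.activity_cap}")
    if not cfg.activity_cap > cfg.min_pressure:
        raise ConfigError(
            f"activity cap ({cfg.activity_cap}) must exceed the minimum "
            f"pressure ({cfg.min_pressure})"
        )
    # re-run the Weibull invariants (specs may have been built via replace)
    for spec in (cfg.anatomy_weibull, cfg.threshold_weibull):
        WeibullSpec(spec.shape, spec.scale, spec.location)
    if not 0.35 <= cfg.min_pressure <= 0.7:
        warnings.warn(
            f"minimum pressure {cfg.min_pressure} is far from 0.5; the uterus "
            "maintains a non-zero baseline near 1/20 of peak pressure, so "
            "values near 0.5 are the physiologically reasonable range",
            PlausibilityWarning,
            stacklevel=2,
        )
    return cfg


# --------------------------------------------------------------------------
# Flat key/value config files (YAML or JSON)
# --------------------------------------------------------------------------

# Program-variable aliases accepted in config files.
_ALIASES = {
    "initialpressure": "initial_pressure",
    "minpressure": "min_pressure",
    "timeburst": "burst_duration",
    "timerefractory": "refractory_duration",
    "burstmultiplier": "ap_multiplier",
    "refractorymultiplier": "refractory_multiplier",
}
_WEIBULL_KEYS = {
    "weibullvar1": ("anatomy_weibull", "shape"),
    "weibullvar2": ("anatomy_weibull", "scale"),
    "weibullvar3": ("anatomy_weibull", "location"),
    "weibullvar4": ("threshold_weibull", "shape"),
    "weibullvar5": ("threshold_weibull", "scale"),
    "weibullvar6": ("threshold_weibull", "location"),
}
_INT_FIELDS = {
    "rows", "columns", "timesteps", "burst_duration", "refractory_duration",
    "anatomy_seed", "threshold_seed",
}


def config_from_mapping(d: Mapping) -> SimulationConfig:
    """Build a configuration from a flat mapping.

    Accepts both package field names and the short program-variable names
    (``initialpressure``, ``timeburst``, ``weibullvar1`` ... ``weibullvar6``).
    Missing keys take the default (preset 1 with the default Weibulls).
    """
    kwargs: dict = {}
    weib: dict[str, dict[str, float]] = {}
    for key, value in d.items():
        k = str(key).strip().lower()
        if k in _WEIBULL_KEYS:
            name, part = _WEIBULL_KEYS[k]
            weib.setdefault(name, {})[part] = float(value)
            continue
        k = _ALIASES.get(k, k)
        if k in ("anatomy_weibull", "threshold_weibull"):
            if isinstance(value, Mapping):
                weib[k] = {p: float(v) for p, v in value.items()}
            else:
                shape, scale, location = value
                weib[k] = {"shape": shape, "scale": scale, "location": location}
            continue
        fields = SimulationConfig.__dataclass_fields__
        if k not in fields:
            raise ConfigError(f"unknown configuration key {key!r}")
        kwargs[k] = int(value) if k in _INT_FIELDS else float(value)
    for name, parts in weib.items():
        default = getattr(SimulationConfig(), name)
        kwargs[name] = WeibullSpec(
            parts.get("shape", default.shape),
            parts.get("scale", default.scale),
            parts.get("location", default.location),
        )
    return SimulationConfig(**kwargs)


def config_to_mapping(cfg: SimulationConfig) -> dict:
    """Flatten a configuration to the program-variable key set."""
    a, t = cfg.anatomy_weibull, cfg.threshold_weibull
    return {
        "rows": cfg.rows,
        "columns": cfg.columns,
        "timesteps": cfg.timesteps,
        "initialpressure": cfg.initial_pressure,
        "minpressure": cfg.min_pressure,
        "timeburst": cfg.burst_duration,
        "timerefractory": cfg.refractory_duration,
        "burstmultiplier": cfg.ap_multiplier,
        "refractorymultiplier": cfg.refractory_multiplier,
        "weibullvar1": a.shape,
        "weibullvar2": a.scale,
        "weibullvar3": a.location,
        "weibullvar4": t.shape,
        "weibullvar5": t.scale,
        "weibullvar6": t.location,
        "anatomy_seed": cfg.anatomy_seed,
        "threshold_seed": cfg.threshold_seed,
        "activity_cap": cfg.activity_cap,
    }


def load_config(path) -> SimulationConfig:
    """Load a configuration from a flat YAML or JSON file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)  # YAML is a JSON superset
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return config_from_mapping(data)


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(config_to_mapping(cfg), fh, indent=2)
        else:
            yaml.safe_dump(config_to_mapping(cfg), fh, sort_keys=False)
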
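import numpy as np
import pytest
from hypothesis import given, strategies as st

import uterosim as us
from uterosim.engine import RegionPhase, compute_pressure, initial_state, step


def scalar_oracle(anatomy, threshold, cfg):
    """Independent single-region simulator, written with plain scalars.

    Direct transcription of the narrated rules: a quiescent tissue fires
    when passive tension exceeds threshold, bursts for at most
    burst_duration steps (or until the amplified tension drops below
    threshold), is damped through refractory_duration steps, and sits
    quiescent one step before it can re-fire.  Used as the oracle for the
    vectorized engine.
    """
    p = max(cfg.min_pressure, cfg.initial_pressure)
    phase, age = "Q", 0
    trace = [p]
    activities = [min(cfg.activity_cap, cfg.initial_pressure * anatomy)]
    phases = ["Q"]
    for _ in range(cfg.timesteps):
        passive = p * anatomy
        if phase == "Q":
            if passive > threshold:
                phase, age = "B", 1
            else:
                age += 1
        elif phase == "B":
            if age + 1 > cfg.burst_duration or passive * cfg.ap_multiplier < threshold:
                phase, age = "R", 1
            else:
                age += 1
        else:
            if age + 1 > cfg.refractory_duration:
                phase, age = "Q", 0
            else:
                age += 1
        factor = {"Q": 1.0, "B": cfg.ap_multiplier, "R": cfg.refractory_multiplier}[phase]
        act = min(cfg.activity_cap, max(0.0, passive * factor))
        p = max(cfg.min_pressure, act / anatomy)
        trace.append(p)
        activities.append(act)
        phases.append(phase)
    return np.array(trace), np.array(activities), phases


class TestInitialState:
    def test_activities_scale_with_anatomy(self):
        cfg = us.default_config(1)
        f = us.build_fields(cfg)
        s = initial_state(cfg, f)
        np.testing.assert_allclose(s.activity, 0.5 * f.anatomy)
        assert s.pressure == pytest.approx(0.5)
        assert np.all(s.phase == RegionPhase.QUIESCENT)
        assert np.all(s.phase_age == 0)

    def test_single_strip_starting_pressure(self):
        cfg = us.default_config(9)  # init 1, min 0.6
        f = us.fields_from_matrices([[0.991]], [[0.558]])
        s = initial_state(cfg, f)
        assert s.activity[0, 0] == pytest.approx(0.991)
        assert s.pressure == pytest.approx(1.0)

    def test_floor_engages_at_zero_initial_pressure(self):
        cfg = us.default_config(1).replace(initial_pressure=0.0)
        f = us.build_fields(cfg)
        s = initial_state(cfg, f)
        assert np.all(s.activity == 0)
        assert s.pressure == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        cfg = us.default_config(1)
        f = us.fields_from_matrices([[1.0]], [[0.5]])
        with pytest.raises(ValueError, match="does not match"):
            initial_state(cfg, f)


class TestComputePressure:
    def test_round_trip_of_passive_activities(self):
        cfg = us.default_config(1)
        f = us.build_fields(cfg)
        for p in (0.5, 1.3, 7.0):
            assert compute_pressure(p * f.anatomy, f, cfg) == pytest.approx(p)

    def test_floor(self):
        cfg = us.default_config(1)
        f = us.build_fields(cfg)
        assert compute_pressure(np.zeros((4, 4)), f, cfg) == 0.5

    def test_two_region_hand_value(self):
        cfg = us.default_config(11)  # min pressure 0.5
        f = us.fields_from_matrices([[1.0, 1.0]], [[0.5, 0.5]])
        assert compute_pressure(np.array([[3.0, 0.0]]), f, cfg) == pytest.approx(1.5)


class TestPhaseTransitions:
    def test_floor_above_threshold_ignites(self):
        # passive 0.6 * 0.991 = 0.5946 > 0.558
        cfg = us.default_config(9)
        f = us.fields_from_matrices([[0.991]], [[0.558]])
        s = initial_state(cfg, f).__class__(
            t=0,
            activity=np.array([[0.5946]]),
            pressure=0.6,
            phase=np.full((1, 1), RegionPhase.QUIESCENT, dtype=np.int8),
            phase_age=np.zeros((1, 1), dtype=np.int64),
        )
        s2 = step(s, cfg, f)
        assert s2.phase[0, 0] == RegionPhase.BURSTING

    def test_floor_below_threshold_stays_quiescent(self):
        # passive 0.55 * 0.991 = 0.5451 < 0.558
        cfg = us.default_config(10)
        f = us.fields_from_matrices([[0.991]], [[0.558]])
        s = us.EngineState(
            t=0,
            activity=np.array([[0.55 * 0.991]]),
            pressure=0.55,
            phase=np.full((1, 1), RegionPhase.QUIESCENT, dtype=np.int8),
            phase_age=np.zeros((1, 1), dtype=np.int64),
        )
        s2 = step(s, cfg, f)
        assert s2.phase[0, 0] == RegionPhase.QUIESCENT

    def test_burst_cap_forces_refractory_regardless_of_tension(self):
        cfg = us.default_config(9)
        f = us.fields_from_matrices([[1.0]], [[0.558]])
        s = us.EngineState(
            t=0,
            activity=np.array([[10.0]]),
            pressure=10.0,
            phase=np.full((1, 1), RegionPhase.BURSTING, dtype=np.int8),
            phase_age=np.full((1, 1), cfg.burst_duration, dtype=np.int64),
        )
        s2 = step(s, cfg, f)
        assert s2.phase[0, 0] == RegionPhase.REFRACTORY
        assert s2.activity[0, 0] == pytest.approx(2.0)  # 10 * 0.2
        assert s2.pressure == pytest.approx(2.0)

    def test_quiescent_ignition_amplifies_same_step(self):
        cfg = us.default_config(9)
        f = us.fields_from_matrices([[1.0]], [[0.558]])
        s = us.EngineState(
            t=0,
            activity=np.array([[1.0]]),
            pressure=1.0,
            phase=np.full((1, 1), RegionPhase.QUIESCENT, dtype=np.int8),
            phase_age=np.zeros((1, 1), dtype=np.int64),
        )
        s2 = step(s, cfg, f)
        assert s2.activity[0, 0] == pytest.approx(3.0)
        assert s2.pressure == pytest.approx(3.0)


class TestRun:
    def test_matches_scalar_oracle_step_by_step(self, canonical_config):
        cfg = canonical_config
        f = us.fields_from_matrices([[1.0]], [[0.558]])
        result = us.run(cfg, f)
        trace, acts, phases = scalar_oracle(1.0, 0.558, cfg)
        np.testing.assert_allclose(result.pressure_trace, trace)
        np.testing.assert_allclose(result.activity_tensor[:, 0, 0], acts)
        code = {"Q": 0, "B": 1, "R": 2}
        np.testing.assert_array_equal(
            result.phase_tensor[:, 0, 0], [code[p] for p in phases]
        )

    def test_bistability_of_the_pressure_floor(self):
        """Floor above threshold -> repetitive contractions; below -> one
        initial contraction then a flat trace, even though the initial
        pressure exceeds threshold in both cases."""
        f = us.fields_from_matrices([[0.991]], [[0.558]])
        repetitive = us.run(us.default_config(9), f).pressure_trace
        silent = us.run(us.default_config(10), f).pressure_trace
        assert len(us.detect_contractions(repetitive)) >= 5
        assert len(us.detect_contractions(silent)) == 0
        assert np.all(silent[20:] == 0.55)
        # both traces begin with the same initial contraction
        assert silent[:5].max() > 5

    def test_class1_fixed_point_when_all_subthreshold(self):
        cfg = us.default_config(1).replace(timesteps=50)
        f = us.fields_from_matrices(
            np.full((4, 4), 1.0), np.full((4, 4), 2.0)
        )  # floor tension 0.5 < threshold 2 everywhere
        result = us.run(cfg, f)
        assert np.all(result.pressure_trace == 0.5)
        assert np.all(result.phase_tensor == RegionPhase.QUIESCENT)

    def test_bit_determinism(self):
        cfg = us.default_config(1)
        r1, r2 = us.run(cfg), us.run(cfg)
        np.testing.assert_array_equal(r1.pressure_trace, r2.pressure_trace)
        np.testing.assert_array_equal(r1.activity_tensor, r2.activity_tensor)
        np.testing.assert_array_equal(r1.phase_tensor, r2.phase_tensor)


def _assert_invariants(result):
    cfg, f = result.config, result.fields
    trace = result.pressure_trace
    act = result.activity_tensor
    pha = result.phase_tensor

    # Rule-1 round trip at every recorded step
    recomputed = np.maximum(
        cfg.min_pressure, (act / f.anatomy).mean(axis=(1, 2))
    )
    np.testing.assert_allclose(trace, recomputed, rtol=1e-12)

    # bounds
    assert np.all(act >= 0) and np.all(act <= cfg.activity_cap + 1e-12)
    upper = cfg.activity_cap * np.mean(1.0 / f.anatomy)
    assert np.all(trace >= cfg.min_pressure - 1e-12)
    assert np.all(trace <= upper + 1e-9)

    # phase legality: only Q->B, B->R, R->Q transitions
    legal = {(0, 0), (0, 1), (1, 1), (1, 2), (2, 2), (2, 0)}
    pairs = set(zip(pha[:-1].ravel().tolist(), pha[1:].ravel().tolist()))
    assert pairs <= legal

    # burst run lengths bounded; completed refractory runs have exact length
    flat = pha.reshape(pha.shape[0], -1)
    for r in range(flat.shape[1]):
        col = flat[:, r]
        runs = _run_lengths(col)
        for code, length, complete in runs:
            if code == 1:
                assert length <= cfg.burst_duration
            if code == 2 and complete:
                assert length == max(1, cfg.refractory_duration)


def _run_lengths(col):
    runs = []
    start = 0
    for i in range(1, len(col) + 1):
        if i == len(col) or col[i] != col[start]:
            # a run is "complete" if it ends before the trace does
            runs.append((int(col[start]), i - start, i < len(col)))
            start = i
    return runs


@given(
    preset=st.integers(1, 13),
    anatomy_seed=st.integers(1000, 1999),
    threshold_seed=st.integers(2000, 2999),
)
def test_invariants_hold_across_presets_and_seeds(
    preset, anatomy_seed, threshold_seed
):
    cfg = us.default_config(
        preset, anatomy_seed=anatomy_seed, threshold_seed=threshold_seed
    ).replace(timesteps=120)
    _assert_invariants(us.run(cfg))


def test_invariants_on_canonical_run(canonical_run):
    _assert_invariants(canonical_run)


class TestExports:
    def test_trace_and_metadata_files(self, tmp_path, canonical_run):
        from uterosim.engine import (
            save_activity_csv,
            save_run_metadata,
            save_trace_csv,
        )
        import csv, json

        save_trace_csv(canonical_run, tmp_path / "pressure.csv")
        with open(tmp_path / "pressure.csv") as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == len(canonical_run.pressure_trace)
        assert float(rows[3]["pressure"]) == pytest.approx(10.0)

        save_activity_csv(canonical_run, tmp_path / "activity.csv")
        with open(tmp_path / "activity.csv") as fh:
            arows = list(csv.DictReader(fh))
        assert len(arows) == len(canonical_run.pressure_trace)  # 1x1 grid

        save_run_metadata(canonical_run, tmp_path / "run.json")
        meta = json.loads((tmp_path / "run.json").read_text())
        assert meta["config"]["rows"] == 1
        assert meta["semantics"]["activity_cap"] == 10.0
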
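import dataclasses

import numpy as np
import pytest

from afsim import (
    ModelConfig,
    Substrate,
    TissueState,
    apply_lesion,
    excited_value,
    generate_substrate,
    initialize_state,
    make_fixture,
    run,
    step,
    toy_block_state,
    toy_geometry,
)
from conftest import naive_run


def _cable_substrate(C=12, tau=3, rows=3):
    """Uncoupled cables (nu=0), no dysfunction."""
    cfg = ModelConfig(L=C, nu=0.0, delta=0.0, tau=tau, T=10**6, seed=0)
    zeros = np.zeros((rows, C), dtype=bool)
    return Substrate(config=cfg, vertical_edges=zeros, dysfunctional=zeros.copy())


class TestStepRule:
    def test_all_resting_stays_resting_off_pacing_step(self, small_substrate):
        state = initialize_state(small_substrate)
        state.t = 1  # not a pacing step
        new = step(state, small_substrate)
        assert not new.counters.any()
        assert new.t == 2

    def test_initialize_state_deterministic(self, small_substrate):
        a, b = initialize_state(small_substrate), initialize_state(small_substrate)
        assert np.array_equal(a.counters, b.counters)
        assert a.t == b.t == 0
        assert a.rng.random() == b.rng.random()
        assert a.shape == small_substrate.shape

    def test_single_excited_cell_conducts_both_ways_at_unit_speed(self):
        tau = 3
        sub = _cable_substrate(C=12, tau=tau)
        exc = excited_value(tau)
        state = initialize_state(sub)
        state.t = 1
        state.counters[1, 5] = exc
        new = step(state, sub)
        assert new.counters[1, 4] == exc and new.counters[1, 6] == exc
        assert new.counters[1, 5] == exc - 1  # origin now refractory
        assert new.counters[0].sum() == 0  # no transverse spread at nu=0
        for k in range(2, 5):
            new = step(new, sub)
            assert new.counters[1, 5 - k] == exc and new.counters[1, 5 + k] == exc

    def test_excited_step_then_exactly_tau_refractory_steps(self):
        tau = 4
        sub = _cable_substrate(C=10, tau=tau)
        state = initialize_state(sub)
        state.t = 1
        state.counters[0, 0] = excited_value(tau)
        seq = []
        cur = state
        for _ in range(tau + 3):
            cur = step(cur, sub)
            seq.append(int(cur.counters[0, 0]))
        # tau refractory values then resting
        assert seq[:tau] == list(range(tau, 0, -1))
        assert seq[tau] == 0

    def test_mismatched_shapes_rejected(self, small_substrate):
        other = _cable_substrate(C=5)
        with pytest.raises(ValueError, match="shape"):
            step(initialize_state(other), small_substrate)


class TestAgainstBruteForceOracle:
    """The vectorised update must match an independent plain-loop stepper."""

    @pytest.mark.parametrize(
        "nu,delta,epsilon,tau",
        [
            (0.0, 0.0, 0.0, 3),
            (1.0, 0.0, 0.0, 5),
            (0.4, 0.3, 0.0, 4),   # dysfunction irrelevant at eps=0
            (0.4, 0.3, 1.0, 4),   # dysfunctional cells never conduct
            (0.7, 0.15, 1.0, 2),
        ],
    )
    def test_counters_identical_over_40_steps(self, nu, delta, epsilon, tau):
        cfg = ModelConfig(L=13, nu=nu, delta=delta, epsilon=epsilon, tau=tau, T=17, seed=4)
        sub = generate_substrate(cfg)
        trace = run(sub, 40, record_snapshots="all")
        expected = naive_run(sub, 40)
        for i, grid in enumerate(expected, start=1):
            assert np.array_equal(trace.snapshots[i], grid), f"divergence at step {i}"


class TestRun:
    def test_run_is_deterministic(self):
        cfg = ModelConfig(L=30, nu=0.15, delta=0.1, epsilon=0.3, tau=8, T=40, seed=2)
        sub = generate_substrate(cfg)
        a = run(sub, 300, record_snapshots=[150, 300])
        b = run(sub, 300, record_snapshots=[150, 300])
        assert np.array_equal(a.n_excited, b.n_excited)
        for t in (150, 300):
            assert np.array_equal(a.snapshots[t], b.snapshots[t])

    def test_quiescence_without_pacing(self, small_substrate):
        trace = run(small_substrate, 200, pace=False)
        assert not trace.n_excited.any()

    def test_planar_wavefront_unit_speed(self):
        cfg = ModelConfig(L=40, nu=1.0, delta=0.0, tau=10, T=200, seed=0)
        sub = generate_substrate(cfg)
        trace = run(sub, 40, record_snapshots="all")
        exc = excited_value(cfg.tau)
        for t in range(1, 40):
            cols = np.nonzero((trace.snapshots[t] == exc).any(axis=0))[0]
            assert cols.size == 1 and cols[0] == t - 1

    def test_epsilon_zero_matches_no_dysfunction(self):
        # same seed => same edge map (edges drawn before dysfunction); with
        # eps=0 the dysfunctional mask must not influence the dynamics
        base = dict(L=25, nu=0.2, tau=6, T=30, seed=8)
        a = run(generate_substrate(ModelConfig(delta=0.5, epsilon=0.0, **base)), 200)
        b = run(generate_substrate(ModelConfig(delta=0.0, epsilon=0.7, **base)), 200)
        assert np.array_equal(a.n_excited, b.n_excited)

    def test_delta_zero_never_blocks(self):
        # without dysfunctional cells every stimulated cell fires: the
        # pacemaker-driven rhythm is exactly periodic from the second beat
        cfg = ModelConfig(L=30, nu=0.3, delta=0.0, tau=5, T=60, seed=3)
        sub = generate_substrate(cfg)
        trace = run(sub, 6 * cfg.T)
        beats = trace.n_excited.reshape(6, cfg.T)
        assert np.array_equal(beats[1], beats[2]) and np.array_equal(beats[2], beats[3])

    def test_trace_length_and_bounds(self, small_substrate):
        trace = run(small_substrate, 123)
        assert len(trace.n_excited) == 123
        assert (trace.n_excited >= 0).all()
        assert (trace.n_excited <= small_substrate.n_rows * small_substrate.n_cols).all()


class TestToyCircuit:
    """Two-cable reentry motif: sustain iff ell >= tau/2."""

    @pytest.mark.parametrize("tau", [4, 6])
    def test_sustain_dichotomy_matches_oracle(self, tau):
        for ell in range(1, 5):
            sub = make_fixture("toy_circuit", ell=ell, tau=tau)
            state = toy_block_state(sub, ell)
            trace = run(sub, 150, initial_state=state)
            sustained = bool(trace.n_excited[-10:].any())
            oracle = naive_run(
                sub, 150, initial_counters=state.counters, t0=state.t
            )
            oracle_sustained = bool(oracle[-1].any() or oracle[-5].any())
            assert sustained == oracle_sustained
            assert sustained == (ell >= tau / 2), (ell, tau)

    def test_reentry_cycles_counted(self):
        # ell=3, tau=4: the circuit must complete at least 3 full cycles
        ell, tau = 3, 4
        sub = make_fixture("toy_circuit", ell=ell, tau=tau)
        geo = toy_geometry(ell)
        state = toy_block_state(sub, ell)
        trace = run(sub, 120, record_snapshots="all", initial_state=state)
        exc = excited_value(tau)
        fires = [
            t for t, g in sorted(trace.snapshots.items())
            if g[geo.y_bot, geo.x_d] == exc
        ]
        assert len(fires) >= 3
        period = 2 * (ell + 2)
        assert np.all(np.diff(fires) == period)


class TestLesion:
    def test_rejects_degenerate_rectangle(self, small_substrate):
        with pytest.raises(ValueError, match="width"):
            apply_lesion(small_substrate, 2, 2, 0, 0)

    def test_rejects_out_of_column_bounds(self, small_substrate):
        with pytest.raises(ValueError, match="bounds"):
            apply_lesion(small_substrate, 15, 0, 10, 3)

    def test_wraps_vertically_and_preserves_original(self, small_substrate):
        lesioned = apply_lesion(small_substrate, 3, 18, 4, 5)
        assert not small_substrate.ablated.any()
        rows = {18, 19, 0, 1, 2}
        got = {int(y) for y, x in np.argwhere(lesioned.ablated)}
        assert got == rows
        assert np.array_equal(lesioned.vertical_edges, small_substrate.vertical_edges)

    def test_lesioned_pacemaker_never_fires(self):
        sub = make_fixture("planar", L=20, tau=5, T=30)
        lesioned = apply_lesion(sub, 0, 5, 3, 3)
        trace = run(lesioned, 90, record_snapshots="all")
        for grid in trace.snapshots.values():
            assert not grid[5:8, 0:3].any()

    def test_ablated_cells_inert_everywhere(self):
        cfg = ModelConfig(L=25, nu=0.4, delta=0.1, epsilon=0.2, tau=6, T=40, seed=5)
        sub = apply_lesion(generate_substrate(cfg), 8, 8, 6, 6)
        trace = run(sub, 200, record_snapshots="all")
        for grid in trace.snapshots.values():
            assert not grid[sub.ablated].any()
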
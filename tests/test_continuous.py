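"""Logistic-ODE conversion: corner agreement, steady states, stability."""

import numpy as np
import pytest

from rootscn import (
    activation_level,
    assess_stability,
    build_scn_model,
    find_attractors,
    find_steady_states,
    integrate,
    to_continuous,
)
from rootscn.continuous import integrate_batch, saddle_between
from rootscn.models import reference_profiles


@pytest.fixture(scope="module")
def cont_a(model_a):
    return to_continuous(model_a, h=50.0)


@pytest.fixture(scope="module")
def steady_a(cont_a):
    return find_steady_states(cont_a)


class TestActivation:
    def test_half_activation_at_threshold(self):
        for h in (1.0, 10.0, 500.0):
            assert activation_level(0.5, h, 0.5) == pytest.approx(0.5)

    def test_steep_limit_is_step_like(self):
        assert activation_level(0.6, 200.0, 0.5) == pytest.approx(1.0, abs=1e-8)
        assert activation_level(0.4, 200.0, 0.5) == pytest.approx(0.0, abs=1e-8)

    def test_monotone_in_w(self):
        w = np.linspace(0, 1, 11)
        f = activation_level(w, 50.0, 0.5)
        assert (np.diff(f) > 0).all()

    def test_nonpositive_h_rejected(self):
        with pytest.raises(ValueError):
            activation_level(0.5, 0.0)


class TestConversion:
    def test_w_matches_boolean_output_on_all_corners(self, model_a, cont_a):
        states = np.arange(512, dtype=np.uint64)
        corners = np.array([model_a.decode(int(s)) for s in states], dtype=float)
        w = cont_a.w(corners)
        from rootscn.network import batch_step

        nxt = batch_step(model_a, states)
        expected = np.array([model_a.decode(int(s)) for s in nxt], dtype=float)
        assert np.array_equal(w, expected)

    def test_min_rendering_of_and(self, cont_a, model_a):
        x = np.full(9, 1.0)
        x[model_a.node_index["SCR"]] = 0.3
        assert cont_a.w(x)[model_a.node_index["JKD"]] == pytest.approx(0.3)

    def test_clamped_node_is_pinned(self, model_a):
        cm = to_continuous(model_a.with_clamp("SHR", 0), h=50.0)
        x = cm.pin(np.ones(9))
        assert x[model_a.node_index["SHR"]] == 0.0
        assert cm.rhs(np.ones(9))[model_a.node_index["SHR"]] == 0.0


class TestIntegration:
    def test_stable_state_is_stationary(self, cont_a, steady_a):
        stable = next(s for s in steady_a if s.stable)
        traj = integrate(cont_a, stable.state, t_end=20.0)
        assert np.abs(traj.final - stable.state).max() < 1e-6

    def test_qc_corner_relaxes_to_qc(self, model_a, cont_a):
        qc = np.array(reference_profiles("A").profiles["QC"], dtype=float)
        traj = integrate(cont_a, qc, t_end=50.0)
        assert tuple(int(round(v)) for v in traj.final) == tuple(int(v) for v in qc)

    def test_batch_integrator_agrees_with_solver(self, cont_a):
        x0 = np.array([0.2, 0.9, 0.1, 0.6, 0.8, 0.7, 0.3, 0.4, 0.2])
        fine = integrate(cont_a, x0, t_end=60.0).final
        batch = integrate_batch(cont_a, x0[None, :], t_end=60.0)[0]
        assert np.abs(fine - batch).max() < 1e-4

    def test_bad_initial_state_rejected(self, cont_a):
        with pytest.raises(Exception):
            integrate(cont_a, np.full(9, 2.0))


class TestSteadyStates:
    def test_stable_states_round_to_discrete_attractors(self, model_a, steady_a):
        discrete = set(find_attractors(model_a).fixed_points())
        stable = {s.rounded for s in steady_a if s.stable}
        assert stable == discrete
        for s in steady_a:
            if s.stable:
                corner = np.array(s.rounded, dtype=float)
                assert np.abs(s.state - corner).max() < 0.05

    def test_residuals_below_tolerance(self, steady_a):
        for s in steady_a:
            assert s.residual < 1e-8
            assert (s.state >= 0).all() and (s.state <= 1).all()

    def test_saddle_sits_between_cei_and_qc_at_half_activation(self, model_a, steady_a):
        prof = reference_profiles("A").profiles
        sad = saddle_between(steady_a, prof["QC"], prof["CEI"])
        assert sad is not None and sad.stable is False
        i_m, i_w = model_a.node_index["MGP"], model_a.node_index["WOX5"]
        assert sad.state[i_m] == pytest.approx(0.5, abs=1e-6)
        assert sad.state[i_w] == pytest.approx(0.5, abs=1e-6)
        assert sad.matched_boolean is None

    def test_steady_state_count_weakly_depends_on_h(self, model_a):
        counts = set()
        for h in (20.0, 80.0, 200.0):
            ss = find_steady_states(to_continuous(model_a, h=h))
            counts.add(sum(1 for s in ss if s.stable))
        assert counts == {4}


class TestStability:
    def test_small_perturbations_return_to_stable_state(self, cont_a, steady_a):
        stable = next(s for s in steady_a if s.stable)
        rep = assess_stability(cont_a, stable, n_trials=50, max_perturb=0.01, seed=2)
        assert rep.returned == 50

    def test_saddle_escapes_to_cei_or_qc(self, model_a, cont_a, steady_a):
        prof = reference_profiles("A").profiles
        sad = saddle_between(steady_a, prof["QC"], prof["CEI"])
        rep = assess_stability(cont_a, sad, n_trials=200, max_perturb=0.30, seed=4)
        assert set(rep.terminal_rounded) <= {prof["QC"], prof["CEI"]}
        assert rep.returned < rep.n_trials

    def test_zero_trials_is_an_empty_report(self, cont_a, steady_a):
        rep = assess_stability(cont_a, steady_a[0], n_trials=0, seed=0)
        assert rep.n_trials == 0 and rep.terminal_rounded == {}
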
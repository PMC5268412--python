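import dataclasses

import numpy as np
import pytest

import dmbp
from dmbp.inference import (GridSpec, ParticleEnsemble, extrapolate,
                            grid_filter, init_ensemble, inject_births,
                            predict, run_dmbp, run_pbp, smooth_trace, update)
from dmbp.likelihood import FramePair
from dmbp.params import ModelParams, wrap
from dmbp.readout import object_map
from dmbp.stimulus import render_movie, standard_params
from conftest import tiny_model, tiny_stim


def delta_ensemble(z, n=100, layer="source"):
    states = np.tile(np.asarray(z, dtype=float), (n, 1))
    return ParticleEnsemble(states, np.full(n, 1.0 / n), 0, layer)


def noise_free(**over):
    return tiny_model(D_X=0.0, D_V=0.0, birth_rate=0.0, **over)


class TestPredictExtrapolate:
    def test_zero_step_is_identity(self, rng):
        ens = delta_ensemble([0.1, 0.2, 1.0, -1.0])
        out = predict(ens, 0.0, noise_free(), rng)
        np.testing.assert_allclose(out.states, ens.states)
        np.testing.assert_allclose(out.weights, ens.weights)
        assert out.n_particles == ens.n_particles

    def test_weighted_mean_shifts_by_velocity(self, rng):
        params = tiny_model()
        ens = init_ensemble(params, rng, n=1000)
        ens.states[:, 2] = 1.5
        out = predict(ens, 0.05, params, rng)
        shift = np.sum(out.weights * wrap(out.states[:, 0] - ens.states[:, 0]))
        assert shift == pytest.approx(1.5 * 0.05, abs=0.02)

    def test_extrapolation_compensates_delay(self, rng):
        # noise-free, gamma = 1: (x = 0, u = 2) pushed by tau = 0.1
        # lands at the corrected position x + u tau = 0.2
        ens = delta_ensemble([0.0, 0.0, 2.0, 0.0])
        out = extrapolate(ens, 0.1, noise_free(), rng)
        assert out.layer == "target"
        np.testing.assert_allclose(out.states[:, 0], 0.2)

    def test_forward_then_backward_is_identity(self, rng):
        ens = delta_ensemble([0.3, -0.4, 2.0, 1.0])
        fwd = extrapolate(ens, 0.1, noise_free(), rng)
        back = extrapolate(fwd, -0.1, noise_free(), rng)
        np.testing.assert_allclose(back.states, ens.states, atol=1e-12)


class TestUpdate:
    def test_flat_evidence_keeps_prior(self, rng):
        frame = np.full((32, 32), 0.2)
        pair = FramePair(frame, frame, 0.05)
        params = tiny_model()
        ens = init_ensemble(params, rng, n=200)
        out = update(ens, pair, params, rng)
        np.testing.assert_allclose(out.weights, ens.weights, rtol=1e-9)
        np.testing.assert_array_equal(out.states, ens.states)

    def test_same_seed_same_result(self):
        sp = tiny_stim()
        m = render_movie(sp, 3)
        pair = FramePair(m.frames[9], m.frames[10], m.delta_t)
        params = tiny_model()
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            ens = init_ensemble(params, rng, n=300)
            outs.append(update(ens, pair, params, rng))
        np.testing.assert_array_equal(outs[0].states, outs[1].states)
        np.testing.assert_array_equal(outs[0].weights, outs[1].weights)

    def test_degenerate_evidence_raises(self, rng):
        bad = np.full((16, 16), np.nan)
        pair = FramePair(bad, bad, 0.05)
        params = tiny_model()
        ens = init_ensemble(params, rng, n=50)
        with pytest.raises(RuntimeError, match="degenerate"):
            update(ens, pair, params, rng)

    def test_birth_injection_preserves_normalization(self, rng):
        sp = tiny_stim()
        m = render_movie(sp, 3)
        params = tiny_model()
        ens = init_ensemble(params, rng, n=400)
        out = inject_births(ens, m.frames[10], params, rng)
        assert out.n_particles > 400
        assert out.weights.sum() == pytest.approx(1.0)
        # birth component carries exactly birth_rate of the mass
        assert out.weights[400:].sum() == pytest.approx(params.birth_rate)


class TestRunFilters:
    def test_trace_shapes_and_determinism(self, small_movie, small_model):
        tr1 = run_dmbp(small_movie, small_model, 11)
        tr2 = run_dmbp(small_movie, small_model, 11)
        n = small_model.n_particles
        assert tr1.source_states.shape == (100, n, 4)
        assert tr1.target_states.shape == (100, n, 4)
        np.testing.assert_array_equal(tr1.target_states, tr2.target_states)
        np.testing.assert_array_equal(tr1.target_weights, tr2.target_weights)

    def test_target_tracks_physical_dot_source_lags(self, small_trace,
                                                    small_stim):
        # mid-trajectory: the delay-compensated layer follows the
        # physical position while the source layer lags by ~ V tau
        errs_t, errs_s = [], []
        for k in range(40, 47):
            t = (k + 0.5) * small_stim.delta_t
            x_true = dmbp.dot_position(t, small_stim)[0]
            x_del = dmbp.dot_position(t - 0.1, small_stim)[0]
            errs_t.append(object_map(small_trace, k, "dot") - x_true)
            errs_s.append(object_map(small_trace, k, "dot", "source") - x_del)
        assert abs(np.mean(errs_t)) < 0.06
        assert abs(np.mean(errs_s)) < 0.06

    def test_causality_of_delayed_assimilation(self):
        # perturbing frame k cannot change any output before k + tau/dt
        sp = standard_params(N_X=64, N_Y=64)
        params = tiny_model(delta_t=0.01, tau=0.1, n_particles=300,
                            grid_step=2.0 / 64.0)
        m1 = render_movie(sp, 5)
        frames = m1.frames.copy()
        k_pert = 30
        frames[k_pert] += 0.5
        m2 = dmbp.Movie(frames, m1.delta_t, sp, 5)
        tr1 = run_dmbp(m1, params, 5)
        tr2 = run_dmbp(m2, params, 5)
        d = params.delay_frames
        np.testing.assert_array_equal(tr1.target_states[:k_pert + d],
                                      tr2.target_states[:k_pert + d])
        assert not np.array_equal(tr1.target_states[k_pert + d + 1],
                                  tr2.target_states[k_pert + d + 1])

    def test_weights_normalized_every_frame(self, small_trace):
        np.testing.assert_allclose(small_trace.source_weights.sum(axis=1),
                                   1.0, atol=1e-9)
        np.testing.assert_allclose(small_trace.target_weights.sum(axis=1),
                                   1.0, atol=1e-9)

    def test_pbp_spreads_isotropically_for_static_dot(self):
        sp = tiny_stim(V=0.0, C_flash=0.0, N_T=30)
        params = tiny_model(delta_t=1.0 / 30, tau=3.0 / 30)
        m = render_movie(sp, 2)
        tr = run_pbp(m, params, 2)
        from dmbp.readout import circular_sd

        ens = tr.ensemble(25, "target")
        sd_x = circular_sd(ens.states[:, 0], ens.weights)
        sd_y = circular_sd(ens.states[:, 1], ens.weights)
        assert 0.5 < sd_x / sd_y < 2.0

    def test_push_and_pull_agree_on_tracked_position(self, small_movie,
                                                     small_model):
        push = run_dmbp(small_movie, small_model, 3)
        pull = run_dmbp(small_movie,
                        dataclasses.replace(small_model, mode="pull"), 3)
        diffs = [wrap(object_map(push, k, "dot") - object_map(pull, k, "dot"))
                 for k in range(40, 50)]
        assert abs(np.mean(diffs)) < 0.08  # two histogram bins


class TestSmoothing:
    def test_zero_lag_is_identity(self, small_trace, small_model):
        tr = smooth_trace(small_trace, 0.0, small_model, 1)
        np.testing.assert_array_equal(tr.smoothed_states, tr.target_states)
        assert tr.n_smoothed == tr.n_frames

    def test_positive_lag_truncates_with_warning(self, small_trace,
                                                 small_model):
        with pytest.warns(UserWarning, match="truncates"):
            tr = smooth_trace(small_trace, 0.1, small_model, 1)
        assert tr.n_smoothed == tr.n_frames - 10

    def test_lag_beyond_trace_rejected(self, small_trace, small_model):
        with pytest.raises(ValueError):
            smooth_trace(small_trace, 2.0, small_model, 1)


class TestGridOracle:
    def exact_config(self):
        # deterministic transport (no diffusion, gamma = 1) with grid
        # velocities whose drifts are whole cells: push and pull are
        # algebraically identical orderings there
        sp = tiny_stim()
        params = tiny_model(D_X=0.0, D_V=0.0)
        spec = GridSpec(n_x=20, n_y=4, us=(-2.0, 0.0, 2.0), vs=(0.0,))
        return sp, params, spec

    def test_posterior_mass_sums_to_one(self):
        sp, params, spec = self.exact_config()
        m = render_movie(sp, 1)
        tr = grid_filter(m, params, spec)
        np.testing.assert_allclose(tr.source.sum(axis=(1, 2, 3, 4)), 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(tr.target.sum(axis=(1, 2, 3, 4)), 1.0,
                                   atol=1e-12)

    def test_push_equals_pull_exactly(self):
        sp, params, spec = self.exact_config()
        m = render_movie(sp, 1)
        push = grid_filter(m, params, spec)
        pull = grid_filter(m, dataclasses.replace(params, mode="pull"), spec)
        assert np.max(np.abs(push.target - pull.target)) < 1e-8

    def test_particle_map_within_one_grid_cell_of_oracle(self):
        # coarse noise-free stimulus; compare MAP positions mid-run
        sp = tiny_stim(I_noise=0.0, C_flash=0.0)
        params = tiny_model()
        spec = GridSpec(n_x=32, n_y=8, us=(-2.0, -1.0, 0.0, 1.0, 2.0, 3.0),
                        vs=(0.0,))
        m = render_movie(sp, 0)
        oracle = grid_filter(m, params, spec)
        tr = run_dmbp(m, params, 0)
        cell = 2.0 / spec.n_x
        for k in (8, 11, 14):  # mid-trajectory, past the delayed onset
            x_marg = oracle.target[k].sum(axis=(1, 2, 3))
            x_grid = spec.xs[np.argmax(x_marg)]
            x_pf = object_map(tr, k, "dot")
            assert abs(wrap(x_pf - x_grid)) <= cell + 0.04

    def test_oracle_reproduces_flash_terminated_null(self):
        # with exact inference, the dot estimate snaps back to the
        # terminal position and the velocity collapses once the delayed
        # offset-plus-flash information arrives: no residual lead at the
        # flash maximum (scaled stimulus, same pixel geometry)
        sp = dmbp.StimulusParams(
            T=1.0, N_T=50, N_X=128, N_Y=128, dot_size=0.05, V=1.0,
            dot_start=0.1, dot_stop=0.7, I_noise=0.05,
            flash_frames=(35, 36), flash_dy=0.25,
            condition="flash_terminated")
        params = ModelParams(delta_t=0.02, tau=0.1)
        spec = GridSpec(n_x=100, n_y=32,
                        us=(-2.0, -1.0, 0.0, 1.0, 2.0, 3.0), vs=(0.0,))
        tr = grid_filter(render_movie(sp, 3), params, spec)
        ys = spec.ys
        flash_half = np.abs(wrap(ys - sp.flash_dy)) < np.abs(wrap(ys))
        cell = 2.0 / spec.n_x
        # before the delayed offset arrives the estimate overshoots ...
        pre = tr.target[39].sum(axis=(1, 2, 3))
        assert spec.xs[np.argmax(pre)] > 0.6 + 2 * cell
        # ... and afterwards both estimates collapse onto the terminus
        for k in (41, 42, 43):
            dot = tr.target[k][:, ~flash_half].sum(axis=(1, 2, 3))
            flash = tr.target[k][:, flash_half].sum(axis=(1, 2, 3))
            x_dot = spec.xs[np.argmax(dot)]
            x_flash = spec.xs[np.argmax(flash)]
            assert abs(wrap(x_dot - x_flash)) <= cell
            u_marg = tr.target[k][:, ~flash_half].sum(axis=(0, 1, 3))
            u_mean = (u_marg / u_marg.sum() * np.asarray(spec.us)).sum()
            assert abs(u_mean) < 1.0

    def test_grid_too_large_rejected(self):
        sp, params, _ = self.exact_config()
        m = render_movie(sp, 1)
        big = GridSpec(n_x=400, n_y=400, us=tuple(range(-4, 5)),
                       vs=(0.0, 1.0))
        with pytest.raises(ValueError, match="too large"):
            grid_filter(m, params, big)
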
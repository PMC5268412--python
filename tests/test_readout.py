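import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dmbp
from dmbp.inference import ParticleEnsemble, run_dmbp
from dmbp.params import wrap
from dmbp.readout import (circular_mean, circular_sd, flash_peak_time,
                          histogram, map_position, measure_lag, object_map,
                          precision, processing_delay_ms, sweep,
                          window_histogram)
from dmbp.stimulus import render_movie, standard_params
from conftest import tiny_model


def make_ensemble(xs, weights=None, ys=None, us=None):
    xs = np.asarray(xs, dtype=float)
    n = xs.shape[0]
    states = np.zeros((n, 4))
    states[:, 0] = xs
    if ys is not None:
        states[:, 1] = ys
    if us is not None:
        states[:, 2] = us
    w = np.full(n, 1.0 / n) if weights is None else \
        np.asarray(weights, dtype=float)
    return ParticleEnsemble(states, w / w.sum(), 0, "target")


class TestHistogram:
    def test_delta_ensemble_single_bin(self):
        h = histogram(make_ensemble([0.31] * 20))
        assert np.count_nonzero(h.masses) == 1
        assert h.masses.sum() == pytest.approx(1.0)

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(-0.999, 0.999), min_size=2, max_size=40))
    def test_mass_conserved(self, xs):
        h = histogram(make_ensemble(xs))
        assert h.masses.sum() == pytest.approx(1.0)
        assert np.all(h.masses >= 0)

    def test_uniform_flattens_with_more_particles(self, rng):
        ratios = []
        for n in (500, 50_000):
            h = histogram(make_ensemble(rng.uniform(-1, 1, size=n)))
            ratios.append(h.masses.max() / h.masses.min())
        assert ratios[1] < ratios[0]

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError):
            histogram(make_ensemble([0.0]), n_bins=0)


class TestMapPosition:
    def test_single_occupied_bin(self):
        h = histogram(make_ensemble([0.31] * 5))
        assert map_position(h) == pytest.approx(0.30, abs=0.02)

    def test_tie_breaks_toward_weighted_mean(self):
        # exact two-bin tie at -0.5 and +0.5; hint selects the nearer
        ens = make_ensemble([-0.51, 0.51])
        h = histogram(ens)
        assert map_position(h, mean_hint=0.4) == pytest.approx(0.5, abs=0.04)
        assert map_position(h, mean_hint=-0.4) == pytest.approx(-0.5,
                                                                abs=0.04)

    def test_gaussian_sample_near_true_mean(self, rng):
        ens = make_ensemble(rng.normal(0.3, 0.05, size=4000))
        h = histogram(ens)
        assert map_position(h) == pytest.approx(0.3, abs=0.04)


class TestPrecision:
    def test_uniform_precision_is_sqrt_three(self, rng):
        # SD of a width-2 uniform is 2/sqrt(12), precision sqrt(3)
        ens = make_ensemble(rng.uniform(-1, 1, size=60_000))
        p, capped = precision(ens)
        assert not capped
        assert p == pytest.approx(np.sqrt(3.0), rel=0.02)

    def test_gaussian_sample(self, rng):
        ens = make_ensemble(rng.normal(0.0, 0.1, size=30_000))
        p, capped = precision(ens)
        assert not capped
        assert p == pytest.approx(10.0, rel=0.05)

    def test_degenerate_returns_cap_flagged(self):
        p, capped = precision(make_ensemble([0.2] * 10))
        assert capped and p == pytest.approx(25.0)

    def test_circular_stats_immune_to_wraparound(self, rng):
        # a tight cluster straddling the domain edge
        xs = wrap(rng.normal(1.0, 0.02, size=5000))
        assert abs(wrap(circular_mean(xs, np.full(5000, 1 / 5000)) - 1.0)) \
            < 0.01
        assert circular_sd(xs, np.full(5000, 1 / 5000)) < 0.05


class TestFlashReadout:
    def test_no_flash_rejected(self, small_movie, small_model, small_stim):
        tr = run_dmbp(small_movie, small_model, 4)
        dark = dataclasses.replace(tr, stimulus=dataclasses.replace(
            small_stim, C_flash=0.0))
        with pytest.raises(ValueError, match="no flash"):
            flash_peak_time(dark)

    def test_peak_follows_delayed_flash(self, small_trace, small_stim):
        peak = flash_peak_time(small_trace)
        f0, f1 = small_stim.flash_frames
        d = 10
        assert f0 + d - 2 <= peak <= f1 + d + 5

    def test_processing_delay_near_one_frame(self, small_trace):
        delay = processing_delay_ms(small_trace)
        assert -20.0 <= delay <= 40.0

    def test_flash_map_unbiased(self, small_stim, small_model):
        # no systematic offset of the flash position estimate: the mean
        # signed bias across trials stays within two bins
        biases = []
        for seed in range(4):
            tr = run_dmbp(render_movie(small_stim, seed), small_model, seed)
            peak = flash_peak_time(tr)
            h = window_histogram(tr, range(peak - 2, peak + 3), "flash")
            biases.append(wrap(map_position(h) - small_stim.flash_x))
        assert abs(np.mean(biases)) <= 0.08

    def test_lag_positive_along_motion(self, small_trace):
        lag, peak = measure_lag(small_trace)
        assert lag > 0.08  # at least two bins of lead


class TestLagEquivariance:
    def test_sign_flips_under_mirroring(self, small_model, small_stim):
        # mirror every frame left-right: the raw spatial lead flips sign
        # while the motion-signed lag is preserved on average
        lags, lags_m = [], []
        for seed in range(4):
            movie = render_movie(small_stim, seed)
            mirrored = dmbp.Movie(movie.frames[:, ::-1, :].copy(),
                                  movie.delta_t,
                                  dataclasses.replace(small_stim, V=-1.0),
                                  seed)
            tr = run_dmbp(movie, small_model, seed)
            tr_m = run_dmbp(mirrored, small_model, seed)
            lag, peak = measure_lag(tr)
            lag_m, peak_m = measure_lag(tr_m)
            raw = wrap(object_map(tr, peak, "dot")
                       - object_map(tr, peak, "flash"))
            raw_m = wrap(object_map(tr_m, peak_m, "dot")
                         - object_map(tr_m, peak_m, "flash"))
            assert np.sign(raw) == -np.sign(raw_m)
            lags.append(lag)
            lags_m.append(lag_m)
        assert np.mean(lags_m) == pytest.approx(np.mean(lags), abs=0.08)


class TestSweep:
    def test_single_value_reproducible(self):
        stim = standard_params(N_X=128, N_Y=128)
        model = tiny_model(delta_t=0.01, tau=0.1, n_particles=600,
                           grid_step=2.0 / 128)
        tables = [sweep("speed", [1.0], "standard", n_trials=1, base_seed=9,
                        model=model, stim=stim) for _ in range(2)]
        assert len(tables[0]) == 1
        assert tables[0].loc[0, "seed"] == 9
        assert tables[0].loc[0, "lag"] == tables[1].loc[0, "lag"]

    def test_empty_values_empty_table(self):
        table = sweep("speed", [], "standard", 1, 0)
        assert len(table) == 0

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown sweep"):
            sweep("luminance", [1.0], "standard", 1, 0)
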
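"""Delay-compensating Bayesian filters over noisy movies.

Two estimators share the same machinery:

* the motion-based predictor: a particle filter over z = (x, y, u, v)
  that assimilates each frame pair as soon as it becomes available after
  the fixed sensory delay tau (the *source* layer, a posterior over the
  delayed state), and extrapolates that posterior forward by tau with
  the same transition model (the *target* layer, a posterior over the
  present state);
* the position-based control, identical except that velocity carries no
  predictive information, so the extrapolated posterior spreads
  isotropically instead of along the motion direction.

Both a 'push' ordering (estimate the delayed state, then extrapolate)
and a 'pull' ordering (transport the evidence to the present and update
a present-time belief directly) are implemented, for the particle
filter and for an exact grid filter used as an oracle in tests.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .likelihood import (FramePair, default_window_radius, frame_pair,
                         likelihood_weights)
from .params import ModelParams, StimulusParams, wrap
from .stimulus import Movie
from .transition import transition_noise_vars, transition_sample

Layer = Literal["source", "target", "smoothed"]


@dataclass
class ParticleEnsemble:
    """Weighted particle approximation of a posterior over one frame."""

    states: np.ndarray  # (n, 4): x, y, u, v
    weights: np.ndarray  # (n,), sums to 1
    frame_index: int
    layer: Layer

    def __post_init__(self):
        if self.states.ndim != 2 or self.states.shape[1] != 4:
            raise ValueError("states must have shape (n, 4)")
        if self.weights.shape != (self.states.shape[0],):
            raise ValueError("weights shape mismatch")
        total = self.weights.sum()
        if not np.isfinite(total) or abs(total - 1.0) > 1e-9:
            raise ValueError("weights must be normalized")

    @property
    def n_particles(self) -> int:
        return self.states.shape[0]

    @property
    def ess(self) -> float:
        """Effective sample size 1 / sum(w^2)."""
        return 1.0 / float(np.sum(self.weights**2))


@dataclass
class FilterTrace:
    """Per-frame source- and target-layer ensembles of one filter run."""

    source_states: np.ndarray  # (N_T, n, 4)
    source_weights: np.ndarray  # (N_T, n)
    target_states: np.ndarray
    target_weights: np.ndarray
    model: ModelParams
    stimulus: StimulusParams
    seed: int
    smoothed_states: np.ndarray | None = None
    smoothed_weights: np.ndarray | None = None
    smoothing_lag: float = 0.0
    n_smoothed: int = 0

    @property
    def n_frames(self) -> int:
        return self.source_states.shape[0]

    def ensemble(self, k: int, layer: Layer = "target") -> ParticleEnsemble:
        if layer == "source":
            s, w = self.source_states[k], self.source_weights[k]
        elif layer == "target":
            s, w = self.target_states[k], self.target_weights[k]
        elif layer == "smoothed":
            if self.smoothed_states is None or k >= self.n_smoothed:
                raise IndexError(f"no smoothed ensemble at frame {k}")
            s, w = self.smoothed_states[k], self.smoothed_weights[k]
        else:
            raise ValueError(f"unknown layer {layer!r}")
        return ParticleEnsemble(s, w, k, layer)


def init_ensemble(params: ModelParams, rng: np.random.Generator,
                  n: int | None = None) -> ParticleEnsemble:
    """Pre-data prior: uniform positions, slow-speed-prior velocities."""
    n = params.n_particles if n is None else n
    sig = params.sigma_p_speed
    states = np.empty((n, 4))
    states[:, 0] = rng.uniform(-1.0, 1.0, size=n)
    states[:, 1] = rng.uniform(-1.0, 1.0, size=n)
    states[:, 2] = rng.normal(0.0, sig, size=n)
    states[:, 3] = rng.normal(0.0, sig, size=n)
    return ParticleEnsemble(states, np.full(n, 1.0 / n), 0, "source")


def predict(ens: ParticleEnsemble, dt: float, params: ModelParams,
            rng: np.random.Generator) -> ParticleEnsemble:
    """Advance every particle by one transition step; weights unchanged."""
    return ParticleEnsemble(transition_sample(ens.states, dt, params, rng),
                            ens.weights.copy(), ens.frame_index, ens.layer)


def extrapolate(ens: ParticleEnsemble, dt: float, params: ModelParams,
                rng: np.random.Generator, layer: Layer = "target",
                ) -> ParticleEnsemble:
    """Transport the posterior by dt (forwards or backwards) with the
    transition model; weights unchanged."""
    out = predict(ens, dt, params, rng)
    out.layer = layer
    return out


def systematic_resample(weights: np.ndarray, rng: np.random.Generator,
                        n_out: int | None = None) -> np.ndarray:
    """Indices of a systematic (low-variance) resample of size n_out."""
    n_out = weights.shape[0] if n_out is None else n_out
    positions = (rng.uniform() + np.arange(n_out)) / n_out
    return np.searchsorted(np.cumsum(weights), positions).clip(
        0, weights.shape[0] - 1)


def update(ens: ParticleEnsemble, pair: FramePair, params: ModelParams,
           rng: np.random.Generator, window_radius: float | None = None,
           state_map=None, n_out: int | None = None) -> ParticleEnsemble:
    """Multiply weights by the sensory evidence and renormalize.

    ``state_map`` optionally maps particle states to the states at which
    the evidence is evaluated (used by the pull ordering, where the
    belief lives at the present time but the evidence refers to the
    delayed state).  Systematic resampling (back to ``n_out`` particles)
    is triggered when the effective sample size drops below half of
    ``n_out``, or whenever the ensemble is larger than ``n_out`` (after
    birth injection).
    """
    n_out = ens.n_particles if n_out is None else n_out
    states = ens.states if state_map is None else state_map(ens.states)
    lw = likelihood_weights(pair, states, params, window_radius)
    w = ens.weights * lw
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise RuntimeError("degenerate evidence: total weight not positive")
    w /= total
    out = ParticleEnsemble(ens.states.copy(), w, ens.frame_index, ens.layer)
    if out.ess < n_out / 2 or out.n_particles > n_out:
        out = defensive_resample(out, n_out, params.defensive_fraction, rng)
    return out


def defensive_resample(ens: ParticleEnsemble, n_out: int, beta: float,
                       rng: np.random.Generator) -> ParticleEnsemble:
    """Resample from a defensive mixture of the weights and a uniform.

    Indices are drawn systematically from
    ``(1 - beta) w_i + beta / n`` and the resampled particles keep the
    importance-corrected weights ``w_i / q_i``, so the represented
    distribution is unchanged while low-mass modes (an occluded or
    momentarily outweighed object) keep a share of the particle budget
    and can rebound when their evidence returns.  ``beta = 0`` is plain
    systematic resampling with equal output weights.
    """
    n_in = ens.n_particles
    q = (1.0 - beta) * ens.weights + beta / n_in
    idx = systematic_resample(q, rng, n_out)
    w = ens.weights[idx] / q[idx]
    return ParticleEnsemble(ens.states[idx], w / w.sum(),
                            ens.frame_index, ens.layer)


def inject_births(ens: ParticleEnsemble, frame: np.ndarray,
                  params: ModelParams, rng: np.random.Generator,
                  forward: bool = False) -> ParticleEnsemble:
    """Augment the ensemble with the birth component of the transition.

    With probability ``birth_rate`` per frame the state prior allows a
    new, unpredicted object: uniform position, slow-speed-prior
    velocity.  The particle representation samples the birth positions
    from the energy of the incoming frame (a detection proposal) and
    corrects the weights by the exact importance ratio
    uniform-density / proposal-density, so the represented mixture is
    still (1 - eps) * dynamics + eps * pre-data prior.
    """
    eps = params.birth_rate
    if eps <= 0:
        return ens
    m = max(1, int(round(0.25 * ens.n_particles)))
    n_x, n_y = frame.shape
    energy = frame**2
    total = energy.sum()
    if total <= 0:
        return ens
    pixel_area = (2.0 / n_x) * (2.0 / n_y)
    e_norm = energy / total
    # position proposal: a mixture of energy-weighted detections, a
    # blurred-detection component (populating the surround of bright
    # structure) and a uniform floor; mixture densities are exact and
    # the uniform floor bounds every importance ratio
    from scipy.ndimage import gaussian_filter

    sigma_blur = 0.06  # space units
    e_blur = gaussian_filter(e_norm, sigma_blur * n_x / 2.0, mode="wrap")
    e_blur /= e_blur.sum()
    w_det, w_blur, w_uni = 0.4, 0.3, 0.3
    p = (w_det * e_norm.ravel() + w_blur * e_blur.ravel()
         + w_uni / energy.size)
    idx = rng.choice(p.size, size=m, p=p)
    ix, iy = np.unravel_index(idx, (n_x, n_y))
    sig = params.sigma_p_speed
    # velocity proposal: equal mixture of a static-biased component
    # (newcomers such as a flash tend to be still) and the full prior
    sig_q = 0.3 * params.grid_step / params.delta_t
    states = np.empty((m, 4))
    states[:, 0] = -1.0 + 2.0 * (ix + rng.uniform(size=m)) / n_x
    states[:, 1] = -1.0 + 2.0 * (iy + rng.uniform(size=m)) / n_y
    narrow = rng.uniform(size=m) < 0.5
    sig_draw = np.where(narrow, sig_q, sig)
    states[:, 2] = rng.normal(0.0, 1.0, size=m) * sig_draw
    states[:, 3] = rng.normal(0.0, 1.0, size=m) * sig_draw
    q_pos = p[idx] / pixel_area  # proposal density per unit area
    v = (1.0 / 4.0) / q_pos  # uniform birth density / proposal density
    # exact velocity importance ratio: prior / mixture proposal
    sq = states[:, 2] ** 2 + states[:, 3] ** 2

    def gauss2(s2, q=sq):
        return np.exp(-q / (2 * s2)) / (2 * np.pi * s2)

    q_vel = 0.5 * gauss2(sig_q**2) + 0.5 * gauss2(sig**2)
    if forward:
        # pull ordering: the detection lives at the delayed time; assert
        # the birth at the present time via the deterministic transport
        # (x + u tau, gamma u).  The map is linear with constant
        # Jacobian, which cancels in the normalization below.
        gamma = params.gamma
        states_now = states.copy()
        states_now[:, 0] = wrap(states[:, 0] + states[:, 2] * params.tau)
        states_now[:, 1] = wrap(states[:, 1] + states[:, 3] * params.tau)
        states_now[:, 2] = gamma * states[:, 2]
        states_now[:, 3] = gamma * states[:, 3]
        sq_now = states_now[:, 2] ** 2 + states_now[:, 3] ** 2
        v *= gauss2(sig**2, sq_now) / q_vel
        states = states_now
    else:
        v *= gauss2(sig**2) / q_vel
    v *= eps / v.sum()
    all_states = np.concatenate([ens.states, states])
    all_w = np.concatenate([ens.weights * (1.0 - eps), v])
    return ParticleEnsemble(all_states, all_w / all_w.sum(),
                            ens.frame_index, ens.layer)


def _pull_back_map(params: ModelParams):
    """Deterministic inverse of the mean transport over tau.

    Used by the pull ordering to evaluate delayed evidence at
    present-time particles: the particle (x, u) is mapped back to the
    delayed state (x - u/gamma * tau, u/gamma) along the noise-free mean
    path.  Without velocity transport the position maps to itself.
    """
    tau = params.tau
    gamma = params.gamma

    def back(states: np.ndarray) -> np.ndarray:
        out = states.copy()
        if gamma > 0:
            out[:, 2] = states[:, 2] / gamma
            out[:, 3] = states[:, 3] / gamma
        if params.velocity_predictive:
            out[:, 0] = wrap(states[:, 0] - out[:, 2] * tau)
            out[:, 1] = wrap(states[:, 1] - out[:, 3] * tau)
        return out

    return back


def run_dmbp(movie: Movie, params: ModelParams, seed: int) -> FilterTrace:
    """Run the delay-compensating motion-based filter on a movie.

    At frame k the source layer assimilates the frame pair
    (k - d - 1, k - d) where d = tau / delta_t, i.e. the newest frames
    that have crossed the sensory delay; the earliest part of the
    trajectory is necessarily missed.  The target layer is the source
    posterior extrapolated by +tau.  In pull mode the target belief is
    updated directly with back-transported evidence; the two orderings
    agree up to the commutation of transport and evidence multiplication
    (exactly, in the noise-free limit).
    """
    d = params.delay_frames
    n_t = movie.n_frames
    if n_t < d + 2:
        raise ValueError("movie shorter than the sensory delay")
    dt = params.delta_t
    if abs(dt - movie.delta_t) > 1e-12:
        raise ValueError("model delta_t does not match the movie")
    # anchor the pixel/frame parameter scale to this movie's sensor
    step = 2.0 / movie.params.N_X
    if abs(step - params.grid_step) > 1e-12:
        params = dataclasses.replace(params, grid_step=step)
    rng = np.random.default_rng(seed)
    window = default_window_radius(movie.params)
    n = params.n_particles
    src_s = np.empty((n_t, n, 4))
    src_w = np.empty((n_t, n))
    tgt_s = np.empty((n_t, n, 4))
    tgt_w = np.empty((n_t, n))

    if params.mode == "push":
        ens = init_ensemble(params, rng)
        for k in range(n_t):
            if k > 0:
                ens = predict(ens, dt, params, rng)
            ens.frame_index = k
            if k >= d + 1:
                ens = inject_births(ens, movie.frames[k - d], params, rng)
                ens = update(ens, frame_pair(movie, k - d), params, rng,
                             window, n_out=params.n_particles)
            tgt = extrapolate(ens, params.tau, params, rng)
            src_s[k], src_w[k] = ens.states, ens.weights
            tgt_s[k], tgt_w[k] = tgt.states, tgt.weights
    else:  # pull
        back = _pull_back_map(params)
        ens = init_ensemble(params, rng)
        ens = extrapolate(ens, params.tau, params, rng)
        for k in range(n_t):
            if k > 0:
                ens = predict(ens, dt, params, rng)
            ens.frame_index = k
            if k >= d + 1:
                ens = inject_births(ens, movie.frames[k - d], params, rng,
                                    forward=True)
                ens = update(ens, frame_pair(movie, k - d), params, rng,
                             window, state_map=back,
                             n_out=params.n_particles)
            src = extrapolate(ens, -params.tau, params, rng, layer="source")
            src_s[k], src_w[k] = src.states, src.weights
            tgt_s[k], tgt_w[k] = ens.states, ens.weights

    return FilterTrace(src_s, src_w, tgt_s, tgt_w, params, movie.params, seed)


def pbp_params(params: ModelParams) -> ModelParams:
    """Position-based control: infinite velocity diffusion (velocity has
    no predictive precision) and isotropic position diffusion D_X."""
    return dataclasses.replace(params, D_V=np.inf, velocity_predictive=False)


def run_pbp(movie: Movie, params: ModelParams, seed: int) -> FilterTrace:
    """Run the position-based control model (no motion extrapolation)."""
    return run_dmbp(movie, pbp_params(params), seed)


def smooth_trace(trace: FilterTrace, tau_s: float, params: ModelParams,
                 rng: np.random.Generator | int | None = None) -> FilterTrace:
    """Postdictive read-out: backward extrapolation by a subjective lag.

    The smoothed ensemble at frame k is the target posterior at frame
    k + tau_s/delta_t transported backwards by tau_s, i.e. the belief
    about the state at physical frame k held tau_s later; outputs are
    realigned to physical time.  Frames within tau_s of the trace end
    have no future belief and are truncated (with a warning).
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    dt = params.delta_t
    s = tau_s / dt
    if abs(s - round(s)) > 1e-9:
        raise ValueError("tau_s must be an integer number of frames")
    s = int(round(s))
    if s < 0:
        raise ValueError("tau_s must be non-negative")
    n_t = trace.n_frames
    n_valid = n_t - s
    if n_valid <= 0:
        raise ValueError("tau_s longer than the whole trace")
    if s > 0:
        warnings.warn(
            f"smoothing truncates the last {s} frames of the trace",
            stacklevel=2)
    sm_s = np.empty((n_valid,) + trace.target_states.shape[1:])
    sm_w = np.empty((n_valid,) + trace.target_weights.shape[1:])
    for k in range(n_valid):
        ens = trace.ensemble(k + s, "target")
        sm = extrapolate(ens, -tau_s, params, rng, layer="smoothed")
        sm_s[k], sm_w[k] = sm.states, sm.weights
    return dataclasses.replace(trace, smoothed_states=sm_s,
                               smoothed_weights=sm_w, smoothing_lag=tau_s,
                               n_smoothed=n_valid)


# ---------------------------------------------------------------------------
# Exact grid filter (oracle)
# ---------------------------------------------------------------------------

_MAX_GRID_CELLS = 2_000_000


@dataclass
class GridSpec:
    """Discretization of the state space for the exact filter."""

    n_x: int = 16
    n_y: int = 16
    us: tuple[float, ...] = (-4.0, -2.0, 0.0, 2.0, 4.0)
    vs: tuple[float, ...] = (0.0,)

    @property
    def xs(self) -> np.ndarray:
        return -1.0 + 2.0 * (np.arange(self.n_x) + 0.5) / self.n_x

    @property
    def ys(self) -> np.ndarray:
        return -1.0 + 2.0 * (np.arange(self.n_y) + 0.5) / self.n_y

    def states(self) -> np.ndarray:
        """All grid states as an (n, 4) array (x fastest varying last)."""
        gx, gy, gu, gv = np.meshgrid(self.xs, self.ys, np.asarray(self.us),
                                     np.asarray(self.vs), indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gu.ravel(), gv.ravel()],
                        axis=1)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (self.n_x, self.n_y, len(self.us), len(self.vs))


@dataclass
class GridTrace:
    """Per-frame exact posteriors on the grid."""

    spec: GridSpec
    source: np.ndarray  # (N_T, *spec.shape)
    target: np.ndarray


def _axis_kernel(points: np.ndarray, shift: float, var: float,
                 circular: bool) -> np.ndarray:
    """Row-stochastic 1D transition matrix K[i, j] = p(point_j | point_i).

    For var = 0 the shift must land exactly on the grid (an integer roll
    on circular axes, an exact match otherwise)."""
    n = points.shape[0]
    if circular:
        step = 2.0 / n
        if var == 0.0:
            r = shift / step
            if abs(r - round(r)) > 1e-9:
                raise ValueError("zero-variance shift off the grid")
            return np.roll(np.eye(n), int(round(r)), axis=1)
        d = wrap(points[None, :] - points[:, None] - shift)
        ks = 2.0 * np.arange(-3, 4)
        k = np.exp(-(d[..., None] + ks) ** 2 / (2.0 * var)).sum(-1)
    else:
        if var == 0.0:
            k = np.isclose(points[None, :], shift * points[:, None],
                           atol=1e-12).astype(float)
            bad = k.sum(1) == 0
            if bad.any():
                raise ValueError("zero-variance velocity map off the grid")
            return k / k.sum(1, keepdims=True)
        d = points[None, :] - shift * points[:, None]
        k = np.exp(-d**2 / (2.0 * var))
    return k / k.sum(1, keepdims=True)


class GridTransition:
    """Factorized exact transition operator on the grid for one dt."""

    def __init__(self, spec: GridSpec, dt: float, params: ModelParams):
        var_x, var_v = transition_noise_vars(params, dt)
        gamma = params.gamma
        drift = dt if params.velocity_predictive else 0.0
        us, vs = np.asarray(spec.us), np.asarray(spec.vs)
        # one positional kernel per (old) velocity value, per axis
        self.kx = np.stack([_axis_kernel(spec.xs, u * drift, var_x, True)
                            for u in us])  # (n_u, n_x, n_x)
        self.ky = np.stack([_axis_kernel(spec.ys, v * drift, var_x, True)
                            for v in vs])
        self.ku = _axis_kernel(us, gamma, var_v, False)
        self.kv = _axis_kernel(vs, gamma, var_v, False)

    def __call__(self, f: np.ndarray) -> np.ndarray:
        # f indexed (x, y, u, v); position transport conditions on the
        # *old* velocity, then velocities mix independently of position.
        g = np.einsum("xyuv,uxa->ayuv", f, self.kx)
        g = np.einsum("xyuv,vyb->xbuv", g, self.ky)
        g = np.einsum("xyuv,uc->xycv", g, self.ku)
        g = np.einsum("xyuv,vd->xyud", g, self.kv)
        return g


def grid_filter(movie: Movie, params: ModelParams, spec: GridSpec,
                window_radius: float | None = None) -> GridTrace:
    """Exact (up to discretization) posterior recursion on a state grid.

    Serves as a brute-force oracle for the particle filter; both the
    push and pull orderings are available via ``params.mode``.
    """
    n_cells = int(np.prod(spec.shape))
    if n_cells * movie.n_frames > _MAX_GRID_CELLS:
        raise ValueError("grid too large for the exact filter")
    step = 2.0 / movie.params.N_X
    if abs(step - params.grid_step) > 1e-12:
        params = dataclasses.replace(params, grid_step=step)
    d = params.delay_frames
    n_t = movie.n_frames
    t_dt = GridTransition(spec, params.delta_t, params)
    t_tau = GridTransition(spec, params.tau, params)
    eps = params.birth_rate
    # birth component: uniform in position, slow-speed prior in velocity
    sig = params.sigma_p_speed
    pu = np.exp(-np.asarray(spec.us) ** 2 / (2 * sig**2))
    pv = np.exp(-np.asarray(spec.vs) ** 2 / (2 * sig**2))
    p0 = np.ones(spec.shape) * (pu[:, None] * pv[None, :])
    p0 /= p0.sum()

    def step_predict(f):
        g = t_dt(f)
        return (1.0 - eps) * g + eps * p0 if eps > 0 else g
    states = spec.states()
    window = (default_window_radius(movie.params)
              if window_radius is None else window_radius)

    def like(k):
        lw = likelihood_weights(frame_pair(movie, k), states, params, window)
        return lw.reshape(spec.shape)

    src = np.empty((n_t,) + spec.shape)
    tgt = np.empty((n_t,) + spec.shape)
    f = np.full(spec.shape, 1.0 / n_cells)
    if params.mode == "push":
        for k in range(n_t):
            if k > 0:
                f = step_predict(f)
            if k >= d + 1:
                f = f * like(k - d)
            f /= f.sum()
            src[k] = f
            g = t_tau(f)
            tgt[k] = g / g.sum()
    else:  # pull: transport the evidence by tau, update the present belief
        h = t_tau(f)
        h /= h.sum()
        for k in range(n_t):
            if k > 0:
                h = step_predict(h)
            if k >= d + 1:
                h = h * t_tau(like(k - d))
            h /= h.sum()
            tgt[k] = h
            src[k] = h  # the pull ordering has no explicit delayed belief
    return GridTrace(spec, src, tgt)
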
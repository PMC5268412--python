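"""Motion-coherency state transitions: transport, diffusion and damping.

The state is z = (x, y, u, v): position on the torus [-1, 1)^2 and
velocity in space units per second.  Over a step dt the position is
transported by the current velocity and blurred, while the velocity is
damped toward zero by the slow-speed prior and diffused:

    x' = x + u dt + nu_x,   nu_x ~ N(0, D_X |dt|)
    u' = gamma u + nu_u,    nu_u ~ N(0, (sigma_p^-2 + D_V^-1)^-1 |dt|)

and likewise for (y, v).  The diffusion constants D_X, D_V and the
slow-speed prior scale sigma_p are dimensionless numbers on the
pixel-and-frame scale of the sensor: D_X = 1 blurs position by one
pixel per frame (variance D_X |dt| with dt in frames, in pixels^2), and
sigma_p = 3 is a prior of three pixels per frame on speed.  This
per-step basis is the only one on which the damping factor
gamma = (1 + D_V / sigma_p^2)^(-1) is dimensionless, and it reproduces
stable tracking: on a per-second, full-domain scale the same numbers
would blur position by 10% of the visual field every frame and no
object could be followed.

The same kernel serves the per-frame prediction (dt = delta_t), the
delay-compensating extrapolation (dt = +tau) and backward smoothing
(dt < 0, with |dt| entering the noise variances).
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams, wrap


def damping_factor(D_V: float, sigma_p: float) -> float:
    """Velocity damping gamma = 1 / (1 + D_V / sigma_p^2).

    A wide prior (large sigma_p) or vanishing velocity diffusion gives
    gamma ~ 1 (no damping); gamma lies in (0, 1].
    """
    if sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    if D_V < 0:
        raise ValueError("D_V must be non-negative")
    return 1.0 / (1.0 + D_V / sigma_p**2)


def transition_noise_vars(params: ModelParams, dt: float) -> tuple[float, float]:
    """Variances (var_x, var_v) of the transition noise over a step dt.

    ``dt`` is in seconds; the returned variances are in space units^2
    and (space units / s)^2.  On the sensor scale (pixels of size
    ``grid_step``, frames of ``delta_t`` seconds) they are
    ``D_X * |dt|`` and ``(sigma_p^-2 + D_V^-1)^-1 * |dt|`` with dt
    counted in frames.  For D_V = 0 the velocity noise vanishes; for a
    very weak slow-speed prior (sigma_p -> inf) it approaches Brownian
    diffusion D_V |dt|.
    """
    frames = abs(dt) / params.delta_t
    s_x = params.grid_step
    s_u = params.grid_step / params.delta_t  # units/s per px/frame
    var_x = params.D_X * frames * s_x**2
    if params.D_V == 0:
        var_v = 0.0
    else:
        var_v = 1.0 / (params.sigma_p**-2 + 1.0 / params.D_V) \
            * frames * s_u**2
    return var_x, var_v


def transition_sample(z: np.ndarray, dt: float, params: ModelParams,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw one transition step for states ``z`` of shape (..., 4).

    The drift uses the signed ``dt`` (backward transport for dt < 0)
    while the noise variances use |dt|; the damping gamma is applied
    once per call, whatever the step size.  In the position-based
    variant (``velocity_predictive=False``) the velocity never
    transports the position, which therefore diffuses isotropically.
    """
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    var_x, var_v = transition_noise_vars(params, dt)
    gamma = params.gamma if dt != 0 else 1.0  # zero time: identity
    drift = dt if params.velocity_predictive else 0.0
    shape = z.shape[:-1]
    out[..., 0] = z[..., 0] + z[..., 2] * drift
    out[..., 1] = z[..., 1] + z[..., 3] * drift
    if var_x > 0:
        out[..., 0] += rng.normal(0.0, np.sqrt(var_x), size=shape)
        out[..., 1] += rng.normal(0.0, np.sqrt(var_x), size=shape)
    out[..., 0] = wrap(out[..., 0])
    out[..., 1] = wrap(out[..., 1])
    out[..., 2] = gamma * z[..., 2]
    out[..., 3] = gamma * z[..., 3]
    if var_v > 0:
        out[..., 2] += rng.normal(0.0, np.sqrt(var_v), size=shape)
        out[..., 3] += rng.normal(0.0, np.sqrt(var_v), size=shape)
    return out


def _wrapped_normal_logpdf(dx: np.ndarray, var: float, n_wraps: int = 3):
    """Log-density of a wrapped normal on [-1, 1), truncated at +-n_wraps."""
    ks = 2.0 * np.arange(-n_wraps, n_wraps + 1)
    d = dx[..., None] + ks
    log_terms = -d**2 / (2.0 * var) - 0.5 * np.log(2.0 * np.pi * var)
    m = np.max(log_terms, axis=-1)
    return m + np.log(np.sum(np.exp(log_terms - m[..., None]), axis=-1))


def transition_logdensity(z_new: np.ndarray, z_old: np.ndarray, dt: float,
                          params: ModelParams) -> np.ndarray:
    """Log of the Gaussian transition kernel implied by transition_sample.

    Positions use a wrapped normal on the torus (truncated at three
    wraps); velocities an ordinary normal.  In degenerate (zero
    variance) directions the density is -inf off the deterministic
    image and 0 on it (a Dirac component, signalled rather than
    raised).
    """
    z_new = np.asarray(z_new, dtype=np.float64)
    z_old = np.asarray(z_old, dtype=np.float64)
    var_x, var_v = transition_noise_vars(params, dt)
    gamma = params.gamma if dt != 0 else 1.0  # zero time: identity
    drift = dt if params.velocity_predictive else 0.0
    mean_x = z_old[..., 0] + z_old[..., 2] * drift
    mean_y = z_old[..., 1] + z_old[..., 3] * drift
    mean_u = gamma * z_old[..., 2]
    mean_v = gamma * z_old[..., 3]
    out = np.zeros(np.broadcast_shapes(z_new.shape[:-1], z_old.shape[:-1]))
    with np.errstate(divide="ignore"):
        for dim, mean, var, circular in (
            (0, mean_x, var_x, True),
            (1, mean_y, var_x, True),
            (2, mean_u, var_v, False),
            (3, mean_v, var_v, False),
        ):
            d = z_new[..., dim] - mean
            if circular:
                d = wrap(d)
            if var > 0:
                if circular:
                    out = out + _wrapped_normal_logpdf(d, var)
                else:
                    out = out - d**2 / (2.0 * var) - 0.5 * np.log(
                        2.0 * np.pi * var)
            else:
                out = out + np.where(np.isclose(d, 0.0, atol=1e-12),
                                     0.0, -np.inf)
    return out
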
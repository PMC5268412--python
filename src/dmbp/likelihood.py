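"""Motion-energy sensory evidence from a pair of consecutive frames.

Evidence for a candidate state z = (x, y, u, v) is computed over a local
window around (x, y): the current frame is compared with the previous
frame back-translated by (u dt, v dt).  Writing c and p for the two
aligned windows, the log-evidence is the cross-correlation

    log w(z) = sum_window c * p / (2 (sigma_I^2 + sigma_noise^2))

which is the opponent form of the motion-energy detector: with
E(.) = |.|^2 the window energy, c * p = E((c+p)/2) - E((c-p)/2), the
energy along the hypothesized displacement minus the energy of the
constancy violation.  It is maximal when the translation superimposes
the object in both frames, near zero for a misaligned translation, for
pure noise, and for an object that has just disappeared (the evidence
is then simply uninformative rather than punitive).  The gain
1 / (sigma_I^2 + sigma_noise^2) treats the pixels as independent
Gaussian measurements; a larger sigma_I flattens the likelihood and
slows the integration.  A uniform image pair yields equal weight for
every state (no evidence).  Weights are relative (normalized so the
largest is 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from .params import ModelParams, StimulusParams

#: additive weight floor; keeps every particle alive without erasing the
#: relative evidence of strongly outweighed hypotheses (weights are
#: normalized to a maximum of 1, so the floor must sit near the bottom of
#: the double-precision range)
WEIGHT_FLOOR = 1e-300


@dataclass(frozen=True)
class FramePair:
    """Two consecutive frames and the time step between them."""

    prev: np.ndarray
    cur: np.ndarray
    delta_t: float

    def __post_init__(self):
        if self.prev.shape != self.cur.shape:
            raise ValueError("frame shapes differ")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")


@dataclass(frozen=True)
class LikelihoodField:
    """Evidence evaluated on a finite set of candidate states."""

    states: np.ndarray  # (n, 4)
    weights: np.ndarray  # (n,)


def _window_offsets(radius: float, n_x: int, n_y: int):
    """Pixel-spaced window offsets (in space units) within ``radius``."""
    step_x = 2.0 / n_x
    step_y = 2.0 / n_y
    r_px = max(1, int(np.ceil(radius / step_x)))
    r_py = max(1, int(np.ceil(radius / step_y)))
    ox = np.arange(-r_px, r_px + 1) * step_x
    oy = np.arange(-r_py, r_py + 1) * step_y
    gx, gy = np.meshgrid(ox, oy, indexing="ij")
    return gx.ravel(), gy.ravel()


@numba.njit(cache=True)
def _correlation(cur, prev, states, ox, oy, dt):
    """Summed cross-correlation of the aligned windows, per state."""
    n = states.shape[0]
    n_w = ox.shape[0]
    n_x, n_y = cur.shape
    hx = n_x / 2.0
    hy = n_y / 2.0
    corr = np.empty(n)
    for i in range(n):
        x0 = states[i, 0]
        y0 = states[i, 1]
        dx = states[i, 2] * dt
        dy = states[i, 3] * dt
        e = 0.0
        for j in range(n_w):
            xs = x0 + ox[j]
            ys = y0 + oy[j]
            # current frame at (xs, ys)
            fx = (xs + 1.0) * hx - 0.5
            fy = (ys + 1.0) * hy - 0.5
            ix = int(np.floor(fx))
            iy = int(np.floor(fy))
            tx = fx - ix
            ty = fy - iy
            ix0 = ix % n_x
            iy0 = iy % n_y
            ix1 = (ix0 + 1) % n_x
            iy1 = (iy0 + 1) % n_y
            c = ((1 - tx) * ((1 - ty) * cur[ix0, iy0] + ty * cur[ix0, iy1])
                 + tx * ((1 - ty) * cur[ix1, iy0] + ty * cur[ix1, iy1]))
            # previous frame back-translated by the candidate velocity
            fx = (xs - dx + 1.0) * hx - 0.5
            fy = (ys - dy + 1.0) * hy - 0.5
            ix = int(np.floor(fx))
            iy = int(np.floor(fy))
            tx = fx - ix
            ty = fy - iy
            ix0 = ix % n_x
            iy0 = iy % n_y
            ix1 = (ix0 + 1) % n_x
            iy1 = (iy0 + 1) % n_y
            p = ((1 - tx) * ((1 - ty) * prev[ix0, iy0] + ty * prev[ix0, iy1])
                 + tx * ((1 - ty) * prev[ix1, iy0] + ty * prev[ix1, iy1]))
            e += c * p
        corr[i] = e
    return corr


def likelihood_weights(pair: FramePair, states: np.ndarray,
                       params: ModelParams,
                       window_radius: float | None = None) -> np.ndarray:
    """Vectorized motion-energy evidence for states of shape (n, 4).

    ``window_radius`` defaults to 0.05 space units (the dot size used
    throughout); the window is a square of whole pixels covering that
    radius.  Returns strictly positive finite weights.
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.float64))
    if states.size == 0:
        raise ValueError("empty state set")
    radius = 0.05 if window_radius is None else window_radius
    n_x, n_y = pair.cur.shape
    ox, oy = _window_offsets(radius, n_x, n_y)
    corr = _correlation(
        np.ascontiguousarray(pair.cur, dtype=np.float64),
        np.ascontiguousarray(pair.prev, dtype=np.float64),
        states, ox, oy, pair.delta_t)
    scale = 2.0 * (params.sigma_I**2 + params.sigma_noise**2)
    log_w = corr / scale
    # evidence is defined up to a common factor; normalize the largest
    # weight to 1 so the exponential never overflows
    return np.exp(log_w - log_w.max()) + WEIGHT_FLOOR


def likelihood_weight(pair: FramePair, z, params: ModelParams,
                      window_radius: float | None = None) -> float:
    """Evidence for a single candidate state z = (x, y, u, v)."""
    return float(likelihood_weights(pair, np.asarray(z)[None, :], params,
                                    window_radius)[0])


def likelihood_field(pair: FramePair, grid: np.ndarray,
                     params: ModelParams,
                     window_radius: float | None = None) -> LikelihoodField:
    """Evaluate the likelihood on a finite grid of states."""
    grid = np.atleast_2d(np.asarray(grid, dtype=np.float64))
    if grid.size == 0:
        raise ValueError("empty grid")
    return LikelihoodField(grid, likelihood_weights(pair, grid, params,
                                                    window_radius))


def frame_pair(movie, k: int) -> FramePair:
    """The (k-1, k) frame pair of a movie."""
    if k < 1 or k >= movie.n_frames:
        raise ValueError(f"frame index {k} has no predecessor")
    return FramePair(movie.frames[k - 1], movie.frames[k], movie.delta_t)


def default_window_radius(stim: StimulusParams) -> float:
    """Local-window radius matched to the stimulus dot size."""
    return stim.dot_size
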
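"""Synthetic moving-dot + flash movies on a toroidal space-time domain.

Frames are indexed ``frames[k, i, j]`` where axis 1 is the horizontal
coordinate x and axis 2 the vertical coordinate y.  Pixel centres sit at
``x_i = -1 + 2 (i + 1/2) / N_X`` so that the grid is symmetric under the
mirror x -> -x used by the motion-reversal stimulus.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .params import StimulusParams, wrap


@dataclass(frozen=True)
class Movie:
    """A stack of noisy grayscale frames plus the generating parameters."""

    frames: np.ndarray  # (N_T, N_X, N_Y)
    delta_t: float
    params: StimulusParams
    seed: int

    def __post_init__(self):
        p = self.params
        if self.frames.shape != (p.N_T, p.N_X, p.N_Y):
            raise ValueError("frame stack does not match stimulus parameters")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def pixel_centers(n: int) -> np.ndarray:
    """Pixel-centre coordinates covering one period [-1, 1)."""
    return -1.0 + 2.0 * (np.arange(n) + 0.5) / n


def dot_position(t: float, params: StimulusParams):
    """Physical dot position at time ``t`` (seconds).

    Returns ``(x, y)`` on the torus, or ``None`` while the dot is not
    displayed.  Speed ``V`` is in spatial periods per temporal period,
    i.e. the dot moves ``2 V / T`` space units per second.  For the
    reversal condition the trajectory is the left-right mirror of the
    standard one from mid-movie onwards.
    """
    if not 0 <= t < params.T:
        raise ValueError(f"t={t} outside the stimulus interval [0, {params.T})")
    if not params.dot_start <= t <= params.dot_stop:
        return None
    speed = 2.0 * params.V / params.T  # space units per second
    x = wrap(params.x_start + speed * (t - params.dot_start))
    if params.condition == "reversal" and t >= params.T / 2:
        x = wrap(-x)
    return (float(x), 0.0)


def _blob(xc: float, yc: float, amplitude: float, xs: np.ndarray,
          ys: np.ndarray, sigma: float) -> np.ndarray:
    """Isotropic Gaussian luminance blob on the torus."""
    dx = wrap(xs - xc)[:, None]
    dy = wrap(ys - yc)[None, :]
    return amplitude * np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))


def render_movie(params: StimulusParams, seed: int) -> Movie:
    """Render the stimulus movie for any condition.

    Each frame is ``C_dot * dot blob + C_flash * flash blob`` (the flash
    only during its frame interval, at ``(flash_x, flash_dy)``) on a
    zero background with i.i.d. Gaussian pixel noise of std ``I_noise``.
    The blob std is ``dot_size / 2``.  The same seed reproduces the
    movie bit for bit.
    """
    if params.condition == "reversal":
        return reversal_movie(params, seed)
    return Movie(_render_frames(params, seed), params.delta_t, params, seed)


def _render_frames(params: StimulusParams, seed: int,
                   ignore_reversal: bool = False) -> np.ndarray:
    rng = np.random.default_rng(seed)
    xs = pixel_centers(params.N_X)
    ys = pixel_centers(params.N_Y)
    sigma = params.dot_size / 2.0
    f0, f1 = params.flash_frames
    frames = np.empty((params.N_T, params.N_X, params.N_Y), dtype=np.float64)
    base = params if not ignore_reversal else dataclasses.replace(
        params, condition="standard")
    for k in range(params.N_T):
        t = (k + 0.5) * params.delta_t
        frame = rng.normal(0.0, params.I_noise, size=(params.N_X, params.N_Y))
        pos = dot_position(t, base)
        if pos is not None and params.C_dot > 0:
            frame += _blob(pos[0], pos[1], params.C_dot, xs, ys, sigma)
        if f0 <= k <= f1 and params.C_flash > 0:
            frame += _blob(params.flash_x, params.flash_dy, params.C_flash,
                           xs, ys, sigma)
        frames[k] = frame
    return frames


def reversal_movie(params: StimulusParams, seed: int) -> Movie:
    """Standard movie whose second half is mirrored about the vertical axis.

    Frames at t < T/2 are bit-identical to ``render_movie`` with the
    same seed; frames at t >= T/2 are flipped left-right, so the
    horizontal motion reverses at mid-movie while speed magnitude stays
    constant.
    """
    if params.condition != "reversal":
        raise ValueError("reversal_movie requires condition='reversal'")
    frames = _render_frames(params, seed, ignore_reversal=True)
    # frame k covers [k dt, (k+1) dt); mirror frames with centre >= T/2
    ks = (np.arange(params.N_T) + 0.5) * params.delta_t >= params.T / 2
    frames[ks] = frames[ks, ::-1, :]
    return Movie(frames, params.delta_t, params, seed)


def standard_params(condition: str = "standard", **overrides) -> StimulusParams:
    """Stimulus parameters for the named flash-lag condition.

    ``standard`` flashes at mid-trajectory; ``flash_initiated`` at
    motion onset; ``flash_terminated`` at motion offset; ``reversal``
    uses the standard flash timing with a mirrored second half.
    """
    base = StimulusParams(**overrides) if overrides else StimulusParams()
    n_flash = base.flash_frames[1] - base.flash_frames[0] + 1
    dt = base.delta_t
    if condition in ("standard", "reversal"):
        flash = base.flash_frames
    elif condition == "flash_initiated":
        k0 = int(round(base.dot_start / dt))
        flash = (k0, k0 + n_flash - 1)
    elif condition == "flash_terminated":
        # the flash marks the end of the trajectory: it appears at the
        # frame the dot disappears, aligned with its terminal position
        k0 = int(round(base.dot_stop / dt))
        flash = (k0, min(k0 + n_flash - 1, base.N_T - 1))
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return dataclasses.replace(base, condition=condition, flash_frames=flash)
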
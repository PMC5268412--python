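"""Read-outs: position histograms, MAP estimates, precision and the
flash-lag measurement.

The perceived positions of the moving dot and of the flash are read from
one joint posterior by attributing each particle to the nearer object in
the vertical (circular) direction: the dot travels on y = 0 and the
flash sits at y = flash_dy, so the attribution boundary is the
half-plane at flash_dy / 2 (and its antipode).

The spatial lead of the dot over the flash is measured at the moment the
flash is seen most precisely: the frame at which the flash-attributed
posterior's precision (inverse circular standard deviation) peaks.  The
lag is the dot-MAP minus flash-MAP horizontal distance averaged over the
five frames centred on that peak, with positive sign along the motion
direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import FilterTrace, ParticleEnsemble
from .params import StimulusParams, wrap
from .stimulus import Movie

N_BINS_DEFAULT = 50
#: velocity histograms cover +-V_MAX space units per second
V_MAX = 6.0


@dataclass(frozen=True)
class PositionHistogram:
    """Weighted 50-bin histogram of positions over one period [-1, 1)."""

    edges: np.ndarray
    masses: np.ndarray
    axis: str
    frame_index: int

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class LagMeasurement:
    """Flash-lag read-out across trials: dot lead at the flash-precision
    peak, in space units of the [-1, 1) domain."""

    lag: float
    lag_sd: float
    peak_frame: float
    n_trials: int
    per_trial: np.ndarray


def histogram(ens: ParticleEnsemble, n_bins: int = N_BINS_DEFAULT,
              axis: str = "x") -> PositionHistogram:
    """Mass-conserving weighted histogram on the stated axis."""
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    col = {"x": 0, "y": 1}[axis]
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    masses, _ = np.histogram(wrap(ens.states[:, col]), bins=edges,
                             weights=ens.weights)
    total = masses.sum()
    if total > 0:
        masses = masses / total
    return PositionHistogram(edges, masses, axis, ens.frame_index)


def circular_mean(x: np.ndarray, weights: np.ndarray) -> float:
    """Weighted circular mean on the period-2 torus."""
    theta = np.pi * x
    s = np.sum(weights * np.sin(theta))
    c = np.sum(weights * np.cos(theta))
    return float(np.arctan2(s, c) / np.pi)


def circular_sd(x: np.ndarray, weights: np.ndarray) -> float:
    """Weighted standard deviation after recentering on the circular mean.

    Deviations are wrapped to [-1, 1), so the estimate is free of the
    artefacts an ordinary SD shows near the domain edge."""
    mu = circular_mean(x, weights)
    d = wrap(x - mu)
    return float(np.sqrt(np.sum(weights * d**2) / np.sum(weights)))


def map_position(h: PositionHistogram,
                 mean_hint: float | None = None) -> float:
    """Centre of the maximal-mass bin; ties break toward ``mean_hint``
    (the ensemble's weighted circular mean) when provided."""
    m = h.masses
    best = np.flatnonzero(np.isclose(m, m.max(), rtol=1e-12, atol=0.0))
    centers = h.centers[best]
    if len(best) > 1 and mean_hint is not None:
        centers = centers[np.argsort(np.abs(wrap(centers - mean_hint)))]
    return float(centers[0])


def precision(ens: ParticleEnsemble, axis: str = "x",
              n_bins: int = N_BINS_DEFAULT) -> tuple[float, bool]:
    """Inverse circular SD of positions, capped at 1 / bin width.

    Returns ``(precision, capped)``; a degenerate (zero-spread) ensemble
    returns the cap with the flag set."""
    col = {"x": 0, "y": 1}[axis]
    sd = circular_sd(ens.states[:, col], ens.weights)
    cap = n_bins / 2.0  # 1 / (2 / n_bins)
    if sd <= 1.0 / cap:
        return cap, True
    return 1.0 / sd, False


#: attributed posterior mass below which an object counts as undetected.
#: Hypotheses with no luminance support at all sit below ~1e-100 (the
#: evidence suppresses them by hundreds of log-units per frame), while any
#: state that actually latched onto an object retains >= ~1e-9 of the
#: posterior; the threshold sits between the two populations
DETECTION_MASS = 1e-30


def _attribution_mask(ens: ParticleEnsemble, stim: StimulusParams,
                      which: str) -> np.ndarray:
    y = ens.states[:, 1]
    d_dot = np.abs(wrap(y))
    d_flash = np.abs(wrap(y - stim.flash_dy))
    return d_flash < d_dot if which == "flash" else d_flash >= d_dot


def _attributed(ens: ParticleEnsemble, stim: StimulusParams,
                which: str) -> ParticleEnsemble:
    """Sub-ensemble attributed to the dot (y near 0) or the flash
    (y near flash_dy) by circular vertical proximity; weights
    renormalized within the subset."""
    mask = _attribution_mask(ens, stim, which)
    total = ens.weights[mask].sum()
    if not mask.any() or total <= 0:
        raise ValueError(f"no posterior mass attributed to the {which}")
    return ParticleEnsemble(ens.states[mask], ens.weights[mask] / total,
                            ens.frame_index, ens.layer)


def _anchor_ensemble(trace: FilterTrace, k: int, layer: str):
    """The source-layer ensemble whose particles generated layer/k.

    Particle identity is preserved through extrapolation, so read-outs
    of the extrapolated layers attribute each particle to dot or flash
    by its *source-layer* vertical position (before extrapolation blur
    smears the attribution boundary)."""
    if layer == "source":
        return trace.ensemble(k, "source")
    if layer == "target":
        return trace.ensemble(k, "source")
    if layer == "smoothed":
        s = int(round(trace.smoothing_lag / trace.model.delta_t))
        return trace.ensemble(k + s, "source")
    raise ValueError(f"unknown layer {layer!r}")


def attributed_ensemble(trace: FilterTrace, k: int, which: str,
                        layer: str = "target") -> ParticleEnsemble:
    """Dot- or flash-attributed sub-ensemble of one frame of a layer."""
    ens = trace.ensemble(k, layer)
    mask = _attribution_mask(_anchor_ensemble(trace, k, layer),
                             trace.stimulus, which)
    total = ens.weights[mask].sum()
    if not mask.any() or total <= 0:
        raise ValueError(f"no posterior mass attributed to the {which}")
    return ParticleEnsemble(ens.states[mask], ens.weights[mask] / total,
                            ens.frame_index, ens.layer)


def attributed_mass(trace: FilterTrace, k: int, which: str,
                    layer: str = "target") -> float:
    """Posterior mass attributed to the dot or the flash."""
    ens = trace.ensemble(k, layer)
    mask = _attribution_mask(_anchor_ensemble(trace, k, layer),
                             trace.stimulus, which)
    return float(ens.weights[mask].sum())


def object_histogram(trace: FilterTrace, k: int, which: str,
                     layer: str = "target",
                     n_bins: int = N_BINS_DEFAULT) -> PositionHistogram:
    """Horizontal histogram of the dot- or flash-attributed posterior."""
    sub = attributed_ensemble(trace, k, which, layer)
    return histogram(sub, n_bins)


def object_map(trace: FilterTrace, k: int, which: str,
               layer: str = "target", n_bins: int = N_BINS_DEFAULT) -> float:
    """MAP horizontal position of the dot- or flash-attributed posterior."""
    sub = attributed_ensemble(trace, k, which, layer)
    h = histogram(sub, n_bins)
    return map_position(h, circular_mean(sub.states[:, 0], sub.weights))


def map_velocity(trace: FilterTrace, k: int, which: str = "dot",
                 layer: str = "target", n_bins: int = N_BINS_DEFAULT,
                 v_max: float = V_MAX) -> float:
    """MAP horizontal velocity (histogram mode over [-v_max, v_max];
    mass outside the range is ignored)."""
    sub = attributed_ensemble(trace, k, which, layer)
    edges = np.linspace(-v_max, v_max, n_bins + 1)
    masses, _ = np.histogram(sub.states[:, 2], bins=edges,
                             weights=sub.weights)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[np.argmax(masses)])


def flash_peak_time(trace: FilterTrace, layer: str = "target") -> int:
    """Frame of maximal flash-attributed precision.

    The search window runs from flash onset to flash offset + tau + 5
    frames; frames where the flash-attributed posterior mass is below
    the detection threshold do not count (no detection, no precision).
    Raises if the stimulus contains no flash or the flash is never
    detected.
    """
    stim = trace.stimulus
    if stim.C_flash <= 0:
        raise ValueError("stimulus contains no flash")
    d = trace.model.delay_frames
    f0, f1 = stim.flash_frames
    lo = f0
    hi = min(trace.n_frames - 1, f1 + d + 5)
    best_k, best_sd = lo, np.inf
    for k in range(lo, hi + 1):
        if attributed_mass(trace, k, "flash", layer) < DETECTION_MASS:
            continue
        sub = attributed_ensemble(trace, k, "flash", layer)
        sd = circular_sd(sub.states[:, 0], sub.weights)
        # the peak is the frame of minimal SD (maximal precision,
        # uncapped); evidence accumulates, so ties resolve late
        if sd <= best_sd:
            best_k, best_sd = k, sd
    if not np.isfinite(best_sd):
        raise ValueError("flash posterior undefined over the search window")
    return best_k


def window_histogram(trace: FilterTrace, frames, which: str,
                     layer: str = "target",
                     n_bins: int = N_BINS_DEFAULT) -> PositionHistogram:
    """Horizontal histogram pooled over several frames.

    Per-frame attributed histograms (each normalized within its object)
    are averaged with equal weight over the frames where the object is
    detected, i.e. holds at least DETECTION_MASS of the posterior;
    undetected frames contribute nothing."""
    frames = [k for k in frames if 0 <= k < trace.n_frames]
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    pooled = np.zeros(n_bins)
    total = 0
    for k in frames:
        if attributed_mass(trace, k, which, layer) < DETECTION_MASS:
            continue
        sub = attributed_ensemble(trace, k, which, layer)
        pooled += histogram(sub, n_bins).masses
        total += 1
    if total == 0:
        raise ValueError(f"{which} undetected over the whole window")
    return PositionHistogram(edges, pooled / total, "x",
                             frames[len(frames) // 2])


def measure_lag(trace: FilterTrace, movie: Movie | None = None,
                layer: str = "target",
                n_bins: int = N_BINS_DEFAULT) -> tuple[float, int]:
    """Single-trial spatial lead of the dot over the flash.

    The dot- and flash-attributed position histograms are pooled
    (mass-weighted) over the five frames centred on the flash-precision
    peak; the lag is the difference of their MAP positions, signed
    positive along the motion direction.  Returns ``(lag, peak_frame)``.
    """
    stim = trace.stimulus
    peak = flash_peak_time(trace, layer)
    sign = np.sign(stim.V) if stim.V != 0 else 1.0
    if stim.condition == "reversal" and \
            (peak + 0.5) * stim.delta_t >= stim.T / 2:
        sign = -sign
    frames = range(peak - 2, peak + 3)
    h_dot = window_histogram(trace, frames, "dot", layer, n_bins)
    h_flash = window_histogram(trace, frames, "flash", layer, n_bins)
    dot = map_position(h_dot)
    flash = map_position(h_flash)
    return float(wrap(dot - flash) * sign), peak


def processing_delay_ms(trace: FilterTrace, layer: str = "target") -> float:
    """Variable processing delay of the flash response, in milliseconds.

    Time from the arrival of the first informative delayed flash input
    to the frame of maximal flash-attributed precision.  Evidence for a
    static object requires its presence in both frames of a pair, so the
    first delayed pair carrying flash evidence is assimilated at frame
    ``onset + 1 + tau/delta_t``; the peak follows about one frame
    (~10 ms) later, on top of the fixed delay.
    """
    stim = trace.stimulus
    peak = flash_peak_time(trace, layer)
    arrival = stim.flash_frames[0] + 1 + trace.model.delay_frames
    return (peak - arrival) * stim.delta_t * 1000.0


def lag_over_trials(traces: list[FilterTrace]) -> LagMeasurement:
    """Aggregate single-trial lags into the across-trial measurement."""
    lags, peaks = [], []
    for tr in traces:
        lag, peak = measure_lag(tr)
        lags.append(lag)
        peaks.append(peak)
    lags = np.asarray(lags)
    return LagMeasurement(float(lags.mean()), float(lags.std(ddof=1))
                          if len(lags) > 1 else 0.0,
                          float(np.mean(peaks)), len(lags), lags)


def reversal_switch_frame(trace: FilterTrace, layer: str = "target") -> int:
    """First frame at which the dot's MAP horizontal velocity changes sign.

    Searched from the physical reversal (mid-movie) onwards, since the
    reversed motion cannot be detected before it happens; a sign change
    must hold for two consecutive frames to count (the extrapolated
    velocity histogram is noisy).  Raises if the estimate never
    switches.
    """
    stim = trace.stimulus
    if stim.condition != "reversal":
        raise ValueError("trace is not from a reversal stimulus")
    sign0 = np.sign(stim.V) if stim.V != 0 else 1.0
    k_rev = int(round(stim.T / 2 / stim.delta_t))
    for k in range(k_rev, trace.n_frames - 1):
        if map_velocity(trace, k, "dot", layer) * sign0 < 0 and \
                map_velocity(trace, k + 1, "dot", layer) * sign0 < 0:
            return k
    raise ValueError("MAP velocity never changed sign after the reversal")


def sweep(variable: str, values, condition: str, n_trials: int,
          base_seed: int, model=None, stim=None,
          run=None) -> pd.DataFrame:
    """Lag measurements across a parameter sweep.

    ``variable`` is one of ``speed``, ``dot_contrast``, ``flash_contrast``
    or ``flash_duration`` (seconds).  Each row reports one
    (value, trial) pair with its seed, single-trial lag, peak frame and
    flash precision at the peak; per-trial seeds are
    ``base_seed + trial``.
    """
    import dataclasses as _dc

    from .experiments import run_trial
    from .params import ModelParams
    from .stimulus import standard_params

    model = model if model is not None else ModelParams()
    rows = []
    for value in values:
        base = stim if stim is not None else standard_params(condition)
        if variable == "speed":
            sp = _dc.replace(base, V=float(value))
        elif variable == "dot_contrast":
            sp = _dc.replace(base, C_dot=float(value))
        elif variable == "flash_contrast":
            sp = _dc.replace(base, C_flash=float(value))
        elif variable == "flash_duration":
            n_flash = max(1, int(round(float(value) / base.delta_t)))
            f0 = base.flash_frames[0]
            sp = _dc.replace(base, flash_frames=(f0, f0 + n_flash - 1))
        else:
            raise ValueError(f"unknown sweep variable {variable!r}")
        fields = _dc.asdict(sp)
        fields.pop("condition")
        sp = standard_params(condition, **fields)
        for trial in range(n_trials):
            seed = base_seed + trial
            trace = run_trial(sp, model, seed, run=run)
            lag, peak = measure_lag(trace)
            sub = attributed_ensemble(trace, peak, "flash")
            prec, _ = precision(sub)
            rows.append({"variable": variable, "value": value,
                         "condition": condition, "trial": trial,
                         "seed": seed, "lag": lag, "peak_frame": peak,
                         "flash_precision": prec})
    return pd.DataFrame(rows)
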
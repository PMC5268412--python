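"""Model and stimulus parameters.

All spatial quantities live on the periodic domain [-1, 1) in both axes
(one spatial period spans 2 space units); time lives on [0, T).  A speed
of 1 denotes one spatial period per temporal period, i.e. 2 space units
per second for the default T = 1 s.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

Condition = Literal["standard", "flash_initiated", "flash_terminated", "reversal"]

#: Half-width of one spatial period: positions are wrapped to [-1, 1).
DOMAIN_HALF_WIDTH = 1.0


def wrap(x):
    """Wrap coordinates onto the torus [-1, 1)."""
    return (x + 1.0) % 2.0 - 1.0


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the delay-compensating motion estimator.

    Diffusion constants and the slow-speed prior are expressed relative
    to the spatio-temporal period of the stimulus domain.

    Attributes
    ----------
    D_X : position diffusion constant; the transition kernel blurs
        position with variance ``D_X * |dt|`` on the pixel/frame scale
        (see ``grid_step``).
    D_V : velocity diffusion constant (same scale).
    sigma_p : scale of the zero-mean Gaussian prior on slow speeds, in
        pixels per frame.  It induces the velocity damping factor
        ``gamma = 1 / (1 + D_V / sigma_p**2)``.
    tau : fixed sensory delay in seconds; must be an integer number of
        frames.
    delta_t : frame duration in seconds.
    n_particles : ensemble size of the particle filter.
    sigma_I : residual scale of the motion-energy likelihood.
    sigma_noise : assumed sensor noise standard deviation.
    grid_step : sensor pixel pitch in space units (2 / N_X); the
        diffusion constants and sigma_p are dimensionless on this
        pixel-and-frame scale, the only basis on which gamma is
        dimensionless.
    birth_rate : probability per frame that the tracked state is redrawn
        from the pre-data prior (a renewal/birth mixture in the
        transition).  This is what lets an unpredictable, transient
        object such as a flash acquire posterior mass at all.
    defensive_fraction : uniform share of the defensive resampling
        mixture; keeps momentarily outweighed posterior modes
        represented in the particle budget without biasing the
        distribution.
    mode : 'push' (estimate the delayed state, then extrapolate) or
        'pull' (estimate the present state from transported evidence).
        The two orderings are equivalent up to the commutation of
        transport and evidence multiplication.
    velocity_predictive : True for the motion-based model; False yields
        the position-based control in which position diffuses
        isotropically and velocity never transports position.
    """

    D_X: float = 1.0
    D_V: float = 1.0
    sigma_p: float = 3.0
    tau: float = 0.1
    delta_t: float = 0.01
    n_particles: int = 2000
    sigma_I: float = 0.25
    sigma_noise: float = 0.05
    grid_step: float = 2.0 / 256.0
    birth_rate: float = 0.05
    defensive_fraction: float = 0.25
    mode: Literal["push", "pull"] = "push"
    velocity_predictive: bool = True

    def __post_init__(self):
        if self.sigma_p <= 0:
            raise ValueError("sigma_p must be positive")
        if self.D_X < 0 or self.D_V < 0:
            raise ValueError("diffusion constants must be non-negative")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if self.n_particles < 1:
            raise ValueError("n_particles must be at least 1")
        if self.sigma_I <= 0 or self.sigma_noise <= 0:
            raise ValueError("likelihood scales must be positive")
        if self.mode not in ("push", "pull"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not 0 <= self.birth_rate < 1:
            raise ValueError("birth_rate must lie in [0, 1)")

    @property
    def gamma(self) -> float:
        """Velocity damping factor induced by the slow-speed prior."""
        from .transition import damping_factor

        return damping_factor(self.D_V, self.sigma_p)

    @property
    def sigma_p_speed(self) -> float:
        """Slow-speed prior scale converted to space units per second."""
        return self.sigma_p * self.grid_step / self.delta_t

    @property
    def delay_frames(self) -> int:
        """The sensory delay tau expressed in frames.

        Raises
        ------
        ValueError
            If tau is not an integer multiple of delta_t.
        """
        d = self.tau / self.delta_t
        if abs(d - round(d)) > 1e-9:
            raise ValueError(
                f"tau={self.tau} must be an integer number of frames "
                f"(delta_t={self.delta_t})"
            )
        return int(round(d))


@dataclass(frozen=True)
class StimulusParams:
    """Geometry and photometry of the moving-dot + flash stimulus.

    The dot travels along the horizontal mid-line (y = 0) at constant
    speed ``V`` (in spatial periods per temporal period) from
    ``dot_start`` to ``dot_stop`` seconds, starting at x = -0.6 for the
    default timing.  A brief flash of the same profile appears at a
    fixed vertical offset ``flash_dy``, horizontally aligned with the
    dot's position at the centre of the flash interval.
    """

    T: float = 1.0
    N_T: int = 100
    N_X: int = 256
    N_Y: int = 256
    dot_size: float = 0.05
    V: float = 1.0
    dot_start: float = 0.2
    dot_stop: float = 0.8
    I_noise: float = 0.05
    flash_frames: tuple[int, int] = (47, 51)  # inclusive, 0-based
    flash_dy: float = 0.25
    C_dot: float = 1.0
    C_flash: float = 1.0
    condition: Condition = "standard"

    def __post_init__(self):
        if self.N_T < 1 or self.N_X < 1 or self.N_Y < 1:
            raise ValueError("grid dimensions must be positive")
        if not (0 <= self.dot_start <= self.dot_stop <= self.T):
            raise ValueError("need 0 <= dot_start <= dot_stop <= T")
        for c in (self.C_dot, self.C_flash):
            if not 0 <= c <= 1:
                raise ValueError("contrasts must lie in [0, 1]")
        f0, f1 = self.flash_frames
        if not (0 <= f0 <= f1 < self.N_T):
            raise ValueError("flash_frames out of range")
        if self.I_noise < 0:
            raise ValueError("I_noise must be non-negative")

    @property
    def delta_t(self) -> float:
        return self.T / self.N_T

    @property
    def T_f(self) -> float:
        """Flash duration in seconds (inclusive frame count times delta_t)."""
        f0, f1 = self.flash_frames
        return (f1 - f0 + 1) * self.delta_t

    @property
    def x_start(self) -> float:
        """Horizontal position of motion onset."""
        return -0.6

    @property
    def flash_x(self) -> float:
        """Horizontal position of the flash: the dot's position at the
        centre of the flash interval (perfect alignment)."""
        from .stimulus import dot_position

        f0, f1 = self.flash_frames
        t_mid = (f0 + f1 + 1) / 2 * self.delta_t
        pos = dot_position(t_mid, self)
        if pos is None:
            # flash outside the motion interval: align with the nearest
            # end point of the trajectory
            t_clip = min(max(t_mid, self.dot_start), self.dot_stop)
            pos = dot_position(t_clip, self)
        return pos[0]


_PARAM_TYPES = {"model": ModelParams, "stimulus": StimulusParams}


def _from_mapping(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if "flash_frames" in data:
        data = {**data, "flash_frames": tuple(data["flash_frames"])}
    return cls(**data)


def load_config(path: str | Path) -> tuple[ModelParams, StimulusParams]:
    """Read model and stimulus parameters from a TOML or JSON file.

    The file may contain ``[model]`` and/or ``[stimulus]`` tables whose
    keys are the dataclass field names; missing keys keep their default
    values.
    """
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    model = _from_mapping(ModelParams, data.get("model", {}))
    stim = _from_mapping(StimulusParams, data.get("stimulus", {}))
    return model, stim


def dump_config(model: ModelParams, stim: StimulusParams) -> dict:
    """Serializable dict of both parameter sets (JSON-friendly)."""
    return {
        "model": dataclasses.asdict(model),
        "stimulus": dataclasses.asdict(stim),
    }
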
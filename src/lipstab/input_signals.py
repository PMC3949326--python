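"""The three model inputs and the anticipatory eye-position signal.

* retinal drive (Xr): Gaussian receptive fields over the retinotopic grid,
  width growing with eccentricity, gain-modulated by feedback from the
  LIP(PC) map;
* proprioceptive eye position (Xe_PC): a tonic Gaussian bump at the
  *registered* eye position, which holds the pre-saccadic value and updates
  only late after the saccade;
* corollary discharge (Xe_CD): a Gaussian bump at the planned saccade
  displacement, gated by a temporal envelope with a Gaussian rise before
  saccade onset and a slower Gaussian decay after it;
* anticipatory eye position (Xe_FEF): a gain-field transform combining the
  displacement signal with the current eye position into the predicted
  post-saccadic eye position, computed as the diagonal sum of the product
  map Xb_FEF = Xe_CD x Xe_PC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .grid_dynamics import SpatialGrid
from .oculomotor import SaccadeEvent

__all__ = [
    "Stimulus",
    "rf_width",
    "retinal_drive",
    "registered_eye_position",
    "pc_eye_drive",
    "cd_envelope",
    "cd_drive",
    "fef_transform",
]


@dataclass(frozen=True)
class Stimulus:
    """A luminous stimulus segment in head-centered coordinates."""

    position: float   # deg, head-centered
    onset: float      # ms
    offset: float     # ms
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("stimulus offset must follow onset")
        if self.intensity <= 0:
            raise ValueError("stimulus intensity must be positive")


def rf_width(eccentricity: np.ndarray | float, cfg: ModelConfig) -> np.ndarray | float:
    """Receptive-field width (deg) as a linear function of |eccentricity|."""
    return cfg.signals.rf_sigma0 + cfg.signals.rf_slope * np.abs(eccentricity)


def _attention_gain(fb_sum: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """Bounded saturating feedback nonlinearity f(x) = k x / (1 + x)."""
    if not cfg.signals.fb_enabled:
        return np.zeros_like(fb_sum)
    return cfg.signals.fb_gain * fb_sum / (1.0 + fb_sum)


def retinal_drive(stimuli: list[tuple[float, float]], eye_position: float,
                  grid: SpatialGrid, fb: np.ndarray | None,
                  cfg: ModelConfig) -> np.ndarray:
    """Drive onto the retinotopic map from the active stimuli.

    ``stimuli`` holds (head_position, intensity) pairs; the retinal position
    of each is head_position - eye_position.  Each neuron i receives
    I_i = intensity * exp(-(x - c_i)^2 / sigma(c_i)^2) with sigma the
    eccentricity-dependent receptive-field width, gain-modulated by the
    summed LIP(PC) feedback: drive = I * (1 + f(fb)).
    """
    sigma = rf_width(grid.centers, cfg)
    I = np.zeros(grid.n)
    for head_pos, intensity in stimuli:
        x = head_pos - eye_position
        I += intensity * np.exp(-((x - grid.centers) ** 2) / sigma**2)
    if fb is not None:
        I *= 1.0 + _attention_gain(fb, cfg)
    return I


def registered_eye_position(t: float, saccade: SaccadeEvent,
                            cfg: ModelConfig) -> float:
    """Eye position as registered by the proprioceptive signal at time t.

    Holds the pre-saccadic fixation until saccade offset + pc_delay, then
    ramps linearly to the executed post-saccadic position over
    pc_transition ms.
    """
    t0 = saccade.offset + cfg.signals.pc_delay
    if t <= t0:
        return saccade.fixation
    u = min((t - t0) / cfg.signals.pc_transition, 1.0)
    return saccade.fixation + u * saccade.executed_amplitude


def pc_eye_drive(t: float, saccade: SaccadeEvent, grid: SpatialGrid,
                 cfg: ModelConfig) -> np.ndarray:
    """Gaussian activity profile centered on the registered eye position."""
    e = registered_eye_position(t, saccade, cfg)
    return np.exp(-((grid.centers - e) ** 2) / cfg.signals.pc_sigma**2)


def cd_envelope(t: np.ndarray | float, saccade: SaccadeEvent,
                cfg: ModelConfig) -> np.ndarray | float:
    """Temporal envelope of the corollary discharge: peak 1 at saccade onset,
    Gaussian rise (sigma_rise) before, slower Gaussian decay (sigma_decay)
    after."""
    dt = np.asarray(t, dtype=float) - saccade.onset
    sigma = np.where(dt < 0, cfg.signals.cd_sigma_rise, cfg.signals.cd_sigma_decay)
    env = np.exp(-(dt**2) / sigma**2)
    return float(env) if np.ndim(t) == 0 else env


def cd_drive(t: float, saccade: SaccadeEvent, grid: SpatialGrid,
             cfg: ModelConfig, enabled: bool = True) -> np.ndarray:
    """Drive onto the corollary-discharge map: spatial bump at the planned
    displacement (retinotopic saccade vector), gated by the temporal
    envelope.  Disabled (ablated) corollary discharge yields zero drive."""
    if not enabled:
        return np.zeros(grid.n)
    bump = np.exp(-((grid.centers - saccade.cd_amplitude) ** 2)
                  / cfg.signals.cd_sigma**2)
    return cd_envelope(t, saccade, cfg) * bump


def fef_transform(cd: np.ndarray, pc: np.ndarray, grid: SpatialGrid,
                  cfg: ModelConfig) -> np.ndarray:
    """Anticipatory eye-position population from displacement and eye position.

    Builds the 2-D product map Xb_FEF(l, m) = cd(l) * pc(m), sums it along
    the diagonals (a discrete convolution), rescales by the analytic peak of
    the diagonal sum of two unit Gaussian bumps, and resamples the 2n-1
    diagonal bins onto the n-point eye-position grid by linear interpolation.
    The resulting bump peaks at (current eye position + planned displacement)
    and inherits the corollary-discharge temporal envelope.
    """
    diag = np.convolve(cd, pc)  # length 2n - 1; bin h = sum over l+m = h
    # diagonal sum of two Gaussian bumps of widths s1, s2 (index units) has
    # peak amplitude s1*s2*sqrt(pi)/sqrt(s1^2+s2^2) relative to the product
    # of the input peaks
    s1 = cfg.signals.cd_sigma / grid.spacing
    s2 = cfg.signals.pc_sigma / grid.spacing
    norm = s1 * s2 * np.sqrt(np.pi) / np.hypot(s1, s2)
    diag /= norm
    # diagonal bin h encodes position -v + h * spacing; grid cell i encodes
    # -v/2 + i * spacing, i.e. h = i + (n - 1)/2 (half-integer for even n)
    offset = (grid.n - 1) / 2.0
    idx = np.arange(grid.n) + offset
    lo = np.floor(idx).astype(int)
    frac = idx - lo
    return (1.0 - frac) * diag[lo] + frac * diag[np.minimum(lo + 1, 2 * grid.n - 2)]
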
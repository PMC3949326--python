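"""Saccade generation and trial event scheduling.

A saccade is described by its intended amplitude, the stochastically executed
amplitude (endpoint scatter), a smooth position trajectory, and the amplitude
carried by the corollary discharge.  Endpoint scatter is Gaussian with a mean
undershoot, N(0.52 deg, 0.58 deg); the scatter arises on the motor side, so
the corollary discharge does not see the trial-to-trial draw but does reflect
the average undershoot:

    executed = intended - draw,        draw ~ N(0.52, 0.58)
    cd_amplitude = intended - 0.52

Trajectories use a quintic smoothstep (zero velocity and acceleration at both
ends, peak velocity at midflight) with a main-sequence duration law
D = D0 + d1 * |amplitude|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, ModelConfig, OculomotorConfig

__all__ = [
    "SaccadeEvent",
    "TrialEvent",
    "TrialSchedule",
    "sample_scatter",
    "make_trajectory",
    "make_saccade",
    "schedule_events",
]


@dataclass(frozen=True)
class SaccadeEvent:
    """Single source of truth for the timing and kinematics of one saccade."""

    intended_amplitude: float
    executed_amplitude: float
    onset: float                 # ms
    offset: float                # ms
    fixation: float = 0.0        # pre-saccadic eye position, deg
    cd_amplitude: float = 0.0    # displacement carried by corollary discharge

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def landing(self) -> float:
        """Post-saccadic eye position, deg."""
        return self.fixation + self.executed_amplitude

    def eye_position(self, t: np.ndarray | float) -> np.ndarray | float:
        """Eye position at time(s) ``t`` (ms): quintic smoothstep profile."""
        u = (np.asarray(t, dtype=float) - self.onset) / self.duration
        u = np.clip(u, 0.0, 1.0)
        s = u**3 * (10.0 - 15.0 * u + 6.0 * u**2)
        out = self.fixation + self.executed_amplitude * s
        return float(out) if np.ndim(t) == 0 else out


def sample_scatter(rng: np.random.Generator,
                   oculo: OculomotorConfig | None = None) -> float:
    """Draw one signed endpoint error (deg) from N(mean undershoot, scatter SD)."""
    oculo = oculo or OculomotorConfig()
    return float(rng.normal(oculo.undershoot_mean, oculo.scatter_sd))


def make_trajectory(amplitude: float, onset: float,
                    oculo: OculomotorConfig | None = None,
                    fixation: float = 0.0,
                    executed: float | None = None,
                    cd_amplitude: float | None = None) -> SaccadeEvent:
    """Build a saccade with the main-sequence duration law.

    Duration is computed from the *intended* amplitude (the motor plan sets
    the kinematics; scatter only perturbs the endpoint).
    """
    if amplitude == 0:
        raise ConfigurationError("saccade amplitude must be non-zero")
    oculo = oculo or OculomotorConfig()
    duration = oculo.duration_base + oculo.duration_slope * abs(amplitude)
    if executed is None:
        executed = amplitude
    if cd_amplitude is None:
        cd_amplitude = amplitude - np.sign(amplitude) * oculo.undershoot_mean
    return SaccadeEvent(
        intended_amplitude=float(amplitude),
        executed_amplitude=float(executed),
        onset=float(onset),
        offset=float(onset + duration),
        fixation=float(fixation),
        cd_amplitude=float(cd_amplitude),
    )


def make_saccade(amplitude: float, onset: float,
                 oculo: OculomotorConfig | None = None,
                 rng: np.random.Generator | None = None,
                 fixation: float = 0.0) -> SaccadeEvent:
    """Saccade with stochastic endpoint scatter (``rng=None``: no scatter).

    The executed amplitude is intended - draw along the saccade direction;
    the corollary discharge amplitude reflects only the mean undershoot and
    is therefore identical across trials of the same intended amplitude.
    """
    oculo = oculo or OculomotorConfig()
    executed = amplitude
    if rng is not None:
        executed = amplitude - np.sign(amplitude) * sample_scatter(rng, oculo)
    return make_trajectory(amplitude, onset, oculo, fixation=fixation,
                           executed=executed)


@dataclass(frozen=True)
class TrialEvent:
    time: float
    kind: str          # stimulus_on / stimulus_off / displacement / decision_start
    value: float | None = None


@dataclass
class TrialSchedule:
    """Resolved per-trial timeline: stimulus segments and decision timing.

    ``segments`` is a list of (t_on, t_off, head_position, intensity) tuples;
    segments never overlap.  ``c_pre`` is the pre-saccadic stimulus position
    in head-centered degrees (the decision border).
    """

    saccade: SaccadeEvent
    segments: list[tuple[float, float, float, float]]
    events: list[TrialEvent] = field(default_factory=list)
    c_pre: float | None = None
    decision_start: float | None = None
    t_end: float = 0.0

    def stimuli_at(self, t: float) -> list[tuple[float, float]]:
        """Active (head_position, intensity) pairs at time ``t``."""
        return [(pos, inten) for (a, b, pos, inten) in self.segments
                if a <= t < b]


def _check_segments(segments: list[tuple[float, float, float, float]]) -> None:
    for a, b, _, inten in segments:
        if b <= a:
            raise ConfigurationError(f"segment offset {b} not after onset {a}")
        if inten <= 0:
            raise ConfigurationError("stimulus intensity must be positive")
    ordered = sorted(segments)
    for (a1, b1, *_), (a2, _, *_) in zip(ordered, ordered[1:]):
        if a2 < b1:
            raise ConfigurationError(
                f"overlapping contradictory stimulus segments at t={a2}"
            )


def schedule_events(cfg: ModelConfig, saccade: SaccadeEvent,
                    paradigm: str,
                    displacement: float = 0.0,
                    condition: str = "normal",
                    flash_time: float | None = None,
                    flash_position: float | None = None) -> TrialSchedule:
    """Build the event timeline of one trial.

    Parameters
    ----------
    paradigm
        ``"ssd"``: target at the saccade goal for 500 ms before onset, then
        displaced 30 ms after saccade onset (``condition="normal"``) or
        extinguished and reappearing displaced after a 250 ms gap
        (``condition="blank"``).  The decision accumulation starts 28 ms
        after saccade offset when the displaced target reappears during the
        saccade, and 60 ms after reappearance when it reappears after the
        saccade has ended.
        ``"remap"``: a single flash of ``cfg.remap.flash_duration`` ms at
        ``flash_position`` starting at ``flash_time`` (absolute ms).
    """
    events: list[TrialEvent] = []
    if paradigm == "ssd":
        p = cfg.ssd
        target = saccade.fixation + saccade.intended_amplitude
        t_on = saccade.onset - p.pre_duration
        if t_on < 0:
            raise ConfigurationError("pre-saccadic stimulus starts before t=0")
        t_disp = saccade.onset + p.displacement_delay
        displaced = target + displacement
        if condition == "normal":
            reappear = t_disp
            segments = [
                (t_on, t_disp, target, 1.0),
                (t_disp, np.inf, displaced, 1.0),
            ]
            events += [TrialEvent(t_on, "stimulus_on", target),
                       TrialEvent(t_disp, "displacement", displacement)]
        elif condition == "blank":
            reappear = t_disp + p.blank_gap
            segments = [
                (t_on, t_disp, target, 1.0),
                (reappear, np.inf, displaced, 1.0),
            ]
            events += [TrialEvent(t_on, "stimulus_on", target),
                       TrialEvent(t_disp, "stimulus_off"),
                       TrialEvent(reappear, "stimulus_on", displaced)]
        else:
            raise ConfigurationError(f"unknown SSD condition {condition!r}")
        from .decision_readout import accumulation_start  # avoid module cycle
        decision_start = accumulation_start(saccade, reappear, cfg)
        events.append(TrialEvent(decision_start, "decision_start"))
        t_end = decision_start + cfg.decision.timeout + 2 * cfg.grid.dt
        segments = [(a, min(b, t_end), pos, i) for a, b, pos, i in segments]
        sched = TrialSchedule(saccade=saccade, segments=segments,
                              events=events, c_pre=target,
                              decision_start=decision_start, t_end=t_end)
    elif paradigm == "remap":
        if flash_time is None or flash_position is None:
            raise ConfigurationError("remap paradigm needs flash_time/position")
        if flash_time < 0:
            raise ConfigurationError("flash scheduled before simulation start")
        t_off = flash_time + cfg.remap.flash_duration
        segments = [(flash_time, t_off, flash_position, 1.0)]
        events += [TrialEvent(flash_time, "stimulus_on", flash_position),
                   TrialEvent(t_off, "stimulus_off")]
        t_end = max(flash_time + cfg.remap.window[1],
                    saccade.offset + 100.0) + 2 * cfg.grid.dt
        sched = TrialSchedule(saccade=saccade, segments=segments,
                              events=events, t_end=t_end)
    else:
        raise ConfigurationError(f"unknown paradigm {paradigm!r}")
    _check_segments(sched.segments)
    sched.events.sort(key=lambda e: e.time)
    return sched
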
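"""Model configuration: every constant of the simulator in one nested,
serialisable structure.

The configuration is a tree of frozen-by-convention dataclasses.  It can be
round-tripped through YAML (:func:`load_config` / :func:`save_config`) and is
hash-stamped (:func:`config_hash`) into all experiment outputs so that every
result file records exactly which constants produced it.

Parameter provenance falls into three groups, documented per field below and
in ``docs/methods.md``:

* anatomical / paradigm constants (map sizes, visual field, event timings,
  scatter moments) — fixed by the modelled experiments;
* readout constants (diagonal kernel widths and gains, decision bin size,
  accumulator time constant, thresholds) — printed model values;
* calibration constants (map time constant, input kernel widths, corollary
  discharge envelope, proprioceptive update timing, loop gains, match gain)
  — free constants of this implementation, set once by calibrating the
  simulator against the remapping onset and the psychometric biases it is
  meant to reproduce.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "GridConfig",
    "SignalConfig",
    "LipConfig",
    "DecisionConfig",
    "OculomotorConfig",
    "RemapParadigm",
    "SSDParadigm",
    "ModelConfig",
    "default_config",
    "load_config",
    "save_config",
    "config_hash",
]


class ConfigurationError(ValueError):
    """Raised for invalid or contradictory configuration values."""


@dataclass
class GridConfig:
    """Spatial discretisation shared by all maps."""

    n: int = 40            # neurons per 1-D map; 2-D maps are n x n
    v: float = 160.0       # visual field extent in degrees, [-v/2, +v/2]
    dt: float = 1.0        # Euler step, ms
    tau_map: float = 10.0  # leaky-integrator time constant of all maps, ms


@dataclass
class SignalConfig:
    """Input signals: retina, proprioceptive eye position, corollary discharge."""

    # receptive-field width law sigma(e) = sigma0 + slope * |e|, degrees
    rf_sigma0: float = 4.0
    rf_slope: float = 0.05
    # attention-like feedback from the LIP(PC) map onto the retinal drive,
    # f(x) = k * x / (1 + x); not critical for any result, exposed with an
    # off switch
    fb_gain: float = 0.1
    fb_enabled: bool = True
    # proprioceptive eye-position bump width (deg) and its late update:
    # the registered position holds the pre-saccadic value until
    # saccade offset + pc_delay, then ramps linearly to the executed
    # post-saccadic position over pc_transition ms
    pc_sigma: float = 10.0
    pc_delay: float = 80.0
    pc_transition: float = 160.0
    # corollary discharge: spatial bump width (deg) at the planned
    # displacement, temporal envelope = Gaussian rise before saccade onset
    # and slower Gaussian decay after
    cd_sigma: float = 7.0
    cd_sigma_rise: float = 30.0
    cd_sigma_decay: float = 120.0


@dataclass
class LipConfig:
    """LIP circuit: kernels, diagonal readout, remapping loop."""

    # width (deg) of the Gaussian input kernels from the 1-D input maps into
    # the 2-D LIP maps (rows: retinal, columns: eye signal); kernels are
    # normalised so a broad unit bump maps to a unit bump
    input_sigma: float = 6.0
    # diagonal readout into the head-centered population: index-distance
    # Gaussian, printed widths/gains
    diag_sigma: float = 15.0   # index units
    k_diag_pc: float = 0.035   # LIP(PC) -> head-centered / decision weight
    k_diag_cd: float = 0.02    # LIP(CD) -> head-centered / decision weight
    # overall drive gain of the basis-function map (LIP(PC)); sets the
    # weight of the eye-position-gated stream relative to the retinally
    # anchored LIP(CD) response in the head-centered readout
    gain_pc: float = 2.7
    # gain of the anticipatory eye-position signal on the feedforward visual
    # drive of LIP(CD): drive = xr * (1 + gain_ff * fef)
    gain_ff: float = 4.5
    # gain of the remapping feedback (head-centered x anticipatory eye
    # position, injected along the diagonals of LIP(CD))
    k_fb: float = 0.65
    # saturation scale of the feedback transfer fb_sat * tanh(x / fb_sat):
    # linear at operating amplitudes, bounded above, so the recurrent loop
    # cannot run away while the CD envelope is high
    fb_sat: float = 3.0


@dataclass
class DecisionConfig:
    """Template-matching, Poisson noise and competing accumulators."""

    template_step: float = 0.5    # deg, template lattice resolution
    template_span: float = 14.0    # deg, lattice half-width around c_pre
    template_settle: float = 250.0  # ms of fixation used to build a template
    match_gain: float = 0.6      # peak self-match after normalisation
    n_bins: int = 20              # Poisson sub-steps per ms
    s_max: float = 1.0            # spike amplitude
    tau_dn: float = 50.0          # accumulator time constant, ms
    baseline: float = 0.1         # accumulator initial value
    d_thresh: float = 0.6         # decision threshold (printed range 0.3-0.9)
    timeout: float = 100.0        # ms; highest accumulator wins at timeout
    start_post_offset: float = 28.0  # ms after saccade offset (peri-saccadic)
    start_post_stim: float = 60.0    # ms after reappearance (post-saccadic)


@dataclass
class OculomotorConfig:
    """Saccade generation: main sequence, endpoint scatter, CD amplitude."""

    undershoot_mean: float = 0.52  # deg, mean endpoint undershoot
    scatter_sd: float = 0.58       # deg, endpoint scatter SD
    duration_base: float = 23.0    # ms, main-sequence intercept D0
    duration_slope: float = 2.7    # ms/deg, main-sequence slope d1


@dataclass
class RemapParadigm:
    """Predictive-remapping paradigm: 14 deg saccade, 100 ms probe flashes."""

    amplitude: float = 14.0
    rf_position: float = -14.0   # head-centered probe in the present RF
    frf_position: float = 0.0    # head-centered probe in the future RF
    flash_duration: float = 100.0
    flash_from: float = -500.0   # earliest flash time rel. saccade onset, ms
    flash_to: float = 100.0      # latest flash time rel. saccade onset, ms
    flash_step: float = 25.0
    window: tuple[float, float] = (50.0, 350.0)  # ms after flash onset
    onset_fraction: float = 0.1  # response-onset criterion (fraction of max)
    saccade_onset: float = 700.0  # ms from trial start


@dataclass
class SSDParadigm:
    """Saccadic suppression of displacement: 8 deg saccade, target jumps."""

    amplitude: float = 8.0
    displacement_min: float = -4.0
    displacement_max: float = 4.0
    displacement_step: float = 0.5
    displacement_delay: float = 30.0  # ms after saccade onset
    blank_gap: float = 250.0          # ms, gap before displaced reappearance
    pre_duration: float = 500.0       # ms target visible before saccade
    saccade_onset: float = 600.0      # ms from trial start
    n_trials: int = 20                # trials per displacement


@dataclass
class ModelConfig:
    grid: GridConfig = field(default_factory=GridConfig)
    signals: SignalConfig = field(default_factory=SignalConfig)
    lip: LipConfig = field(default_factory=LipConfig)
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    oculomotor: OculomotorConfig = field(default_factory=OculomotorConfig)
    remap: RemapParadigm = field(default_factory=RemapParadigm)
    ssd: SSDParadigm = field(default_factory=SSDParadigm)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def default_config() -> ModelConfig:
    """The reference configuration used throughout the test suite and docs."""
    return ModelConfig()


_SECTIONS = {
    "grid": GridConfig,
    "signals": SignalConfig,
    "lip": LipConfig,
    "decision": DecisionConfig,
    "oculomotor": OculomotorConfig,
    "remap": RemapParadigm,
    "ssd": SSDParadigm,
}


def _from_dict(data: dict[str, Any]) -> ModelConfig:
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        section = dict(data.get(name, {}))
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - valid
        if unknown:
            raise ConfigurationError(
                f"unknown keys in section '{name}': {sorted(unknown)}"
            )
        if "window" in section and section["window"] is not None:
            section["window"] = tuple(section["window"])
        kwargs[name] = cls(**section)
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    return ModelConfig(**kwargs)


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load a YAML configuration; missing sections/keys fall back to defaults."""
    if path is None:
        return default_config()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(data)


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg: ModelConfig) -> str:
    """Short deterministic hash of a configuration, stamped into outputs."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
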
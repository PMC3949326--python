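"""Forward/backward displacement report from LIP activity.

The decision pipeline turns the head-centered population response into a
binary displacement report in seven stages, executed once per millisecond of
the accumulation window:

1. decision input: the head-centered rates (intermediate variant) or the
   printed Gaussian diagonal readout of both LIP maps (lateral variant);
2. template matching by correlation against precalculated fixation
   templates on a 0.5 deg position lattice, m_c = sum_j I_j t^c_j;
3. Poisson spiking noise: each match value is converted to the mean of
   n = 20 Bernoulli sub-steps (spike iff m_c > R * s_max);
4. evidence split at the pre-saccadic stimulus position c_pre:
   m_f = sum_{c >= c_pre} m_c, m_b = sum_{c <= c_pre} m_c (the border bin
   feeds both);
5. competition by simultaneous mutual subtraction;
6. leaky-free accumulation tau_DN d' = m with baseline 0.1, decision at
   threshold crossing;
7. timeout after 100 ms: the larger accumulator wins (seeded coin flip on
   exact ties).

Accumulation starts 28 ms after saccade offset when the displaced stimulus
reappears during the saccade, and 60 ms after stimulus onset when it
reappears after saccade offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig, config_hash
from .lip_circuit import AblationConfig, LipCircuit, Simulator
from .oculomotor import TrialSchedule, make_trajectory

__all__ = [
    "TemplateBank",
    "DecisionTrace",
    "DecisionRunner",
    "build_templates",
    "template_match",
    "poissonize",
    "split_evidence",
    "compete",
    "accumulate",
    "accumulation_start",
]


def accumulation_start(saccade, reappearance_onset: float,
                       cfg: ModelConfig) -> float:
    """Start time (ms) of the evidence accumulation.

    Reappearance strictly before saccade offset counts as peri-saccadic
    (start 28 ms after saccade offset); reappearance at or after saccade
    offset counts as post-saccadic (start 60 ms after stimulus onset).
    """
    if reappearance_onset < saccade.offset:
        return saccade.offset + cfg.decision.start_post_offset
    return reappearance_onset + cfg.decision.start_post_stim


@dataclass(frozen=True)
class TemplateBank:
    """Expected decision-input patterns for stimuli on a 0.5 deg lattice.

    ``templates[k]`` is the steady-fixation decision input for a stimulus at
    ``positions[k]``; ``scale`` normalises the best self-match to the
    configured match gain so that match values land in the dynamic range of
    the Poisson stage.
    """

    positions: np.ndarray
    templates: np.ndarray
    scale: float

    def match(self, i_dp: np.ndarray) -> np.ndarray:
        return self.scale * (self.templates @ i_dp)


_template_cache: dict[tuple, TemplateBank] = {}


def build_templates(cfg: ModelConfig, c_pre: float,
                    variant: str = "intermediate",
                    circuit: LipCircuit | None = None,
                    fixation: float | None = None) -> TemplateBank:
    """Precalculate decision-input templates by running the model itself.

    For each lattice position c (c_pre +/- template_span in template_step
    increments) the model is run to steady state during fixation with a
    stimulus at head-centered position c, and the decision input is
    recorded.  ``fixation`` is the eye position of the template runs; it
    defaults to c_pre, i.e. fixation at the saccade goal, so that the
    templates describe stimuli as seen in the *post-saccadic* view that the
    decision is based on (the retinally anchored part of the LIP(CD)
    response then lines up between template and trial).  Banks are cached
    in memory keyed by configuration hash.
    """
    dcfg = cfg.decision
    if fixation is None:
        fixation = c_pre
    key = (config_hash(cfg), variant, round(c_pre, 6), round(fixation, 6))
    if key in _template_cache:
        return _template_cache[key]
    steps = np.arange(-dcfg.template_span, dcfg.template_span + 1e-9,
                      dcfg.template_step)
    positions = c_pre + steps
    circuit = circuit or LipCircuit(cfg)
    ablation = AblationConfig(variant=variant)
    sim = Simulator(cfg, ablation, circuit)
    # park the saccade far beyond the simulated window so the eye stays at
    # the fixation position and the CD envelope is numerically zero
    far = 1e7
    templates = []
    for c in positions:
        saccade = make_trajectory(8.0, far, cfg.oculomotor, fixation=fixation)
        sched = TrialSchedule(
            saccade=saccade,
            segments=[(0.0, dcfg.template_settle + 1, float(c), 1.0)],
            t_end=dcfg.template_settle,
        )
        state = sim.run(sched)
        templates.append(circuit.decision_input(state).copy())
    templates = np.asarray(templates)
    # equalise template norms: receptive-field widths grow with eccentricity,
    # so raw templates carry an eccentricity-dependent mass that would bias
    # the plain dot-product match toward distal positions; each template is
    # rescaled to unit L2 norm and the common scale maps the best fixation
    # self-match onto the configured match gain
    norms = np.linalg.norm(templates, axis=1)
    templates = templates / norms[:, None]
    scale = dcfg.match_gain / norms.max()
    bank = TemplateBank(positions=positions, templates=templates, scale=scale)
    _template_cache[key] = bank
    return bank


def template_match(i_dp: np.ndarray, bank: TemplateBank) -> np.ndarray:
    """Correlation match of the decision input against every template."""
    if i_dp.shape[0] != bank.templates.shape[1]:
        raise ValueError("decision input length does not match templates")
    return bank.match(i_dp)


def poissonize(m_c: float, rng: np.random.Generator, bins: int = 20,
               s_max: float = 1.0) -> float:
    """Poisson-spike a single match value and return the bin-averaged rate.

    Over ``bins`` sub-steps the neuron spikes (value s_max) iff
    m_c > R * s_max with a fresh uniform R per sub-step; the mean over
    sub-steps is returned, an unbiased estimate of min(m_c / s_max, 1) * s_max.
    """
    r = rng.random(bins)
    return float(np.mean(np.where(m_c > r * s_max, s_max, 0.0)))


def _poissonize_vec(m: np.ndarray, rng: np.random.Generator, bins: int,
                    s_max: float) -> np.ndarray:
    r = rng.random((m.shape[0], bins))
    return s_max * np.mean(m[:, None] > r * s_max, axis=1)


def split_evidence(m: np.ndarray, positions: np.ndarray,
                   c_pre: float) -> tuple[float, float]:
    """Forward/backward evidence sums with the border bin feeding both."""
    lattice_c = positions[np.argmin(np.abs(positions - c_pre))]
    m_f = float(m[positions >= lattice_c].sum())
    m_b = float(m[positions <= lattice_c].sum())
    return m_f, m_b


def compete(m_f: float, m_b: float) -> tuple[float, float]:
    """Mutual subtraction, computed simultaneously from pre-update values."""
    return m_f - m_b, m_b - m_f


@dataclass
class DecisionTrace:
    """Full record of one decision: evidences, accumulators, outcome."""

    c_pre: float
    d_f: list[float] = field(default_factory=list)
    d_b: list[float] = field(default_factory=list)
    m_f: list[float] = field(default_factory=list)
    m_b: list[float] = field(default_factory=list)
    outcome: str | None = None          # "forward" / "backward"
    decision_time: float | None = None  # ms since accumulation start
    timed_out: bool = False


def accumulate(trace: DecisionTrace, m_f: float, m_b: float, dt: float,
               cfg: ModelConfig) -> DecisionTrace:
    """One accumulator step: d += (dt / tau_DN) * m, floored at zero.

    Appends the new accumulator values to the trace and marks the outcome if
    one accumulator reaches the threshold (the larger one wins if both cross
    in the same step).
    """
    dcfg = cfg.decision
    prev_f = trace.d_f[-1] if trace.d_f else dcfg.baseline
    prev_b = trace.d_b[-1] if trace.d_b else dcfg.baseline
    d_f = max(prev_f + (dt / dcfg.tau_dn) * m_f, 0.0)
    d_b = max(prev_b + (dt / dcfg.tau_dn) * m_b, 0.0)
    trace.d_f.append(d_f)
    trace.d_b.append(d_b)
    trace.m_f.append(m_f)
    trace.m_b.append(m_b)
    if trace.outcome is None and max(d_f, d_b) >= dcfg.d_thresh:
        trace.outcome = "forward" if d_f >= d_b else "backward"
        trace.decision_time = len(trace.d_f) * dt
    return trace


class DecisionRunner:
    """Stateful per-trial decision process driven by the simulation loop."""

    def __init__(self, bank: TemplateBank, c_pre: float, cfg: ModelConfig,
                 rng: np.random.Generator):
        if not np.isclose((c_pre - bank.positions[0]) % cfg.decision.template_step,
                          0.0, atol=1e-6):
            # off-lattice borders are snapped by split_evidence; warn once
            import warnings
            warnings.warn(f"decision border c_pre={c_pre} is off the template "
                          "lattice; snapping to the nearest template")
        self.bank = bank
        self.cfg = cfg
        self.rng = rng
        self.trace = DecisionTrace(c_pre=c_pre)
        self.elapsed = 0.0

    @property
    def decided(self) -> bool:
        return self.trace.outcome is not None

    def update(self, i_dp: np.ndarray, dt: float) -> bool:
        """Feed one time step of decision input; returns True once decided."""
        if self.decided:
            return True
        dcfg = self.cfg.decision
        m = self.bank.match(i_dp)
        m_noisy = _poissonize_vec(np.maximum(m, 0.0), self.rng,
                                  dcfg.n_bins, dcfg.s_max)
        m_f, m_b = split_evidence(m_noisy, self.bank.positions,
                                  self.trace.c_pre)
        accumulate(self.trace, *compete(m_f, m_b), dt, self.cfg)
        self.elapsed += dt
        if self.trace.outcome is None and self.elapsed >= dcfg.timeout:
            d_f, d_b = self.trace.d_f[-1], self.trace.d_b[-1]
            if d_f == d_b:
                self.trace.outcome = ("forward" if self.rng.random() < 0.5
                                      else "backward")
            else:
                self.trace.outcome = "forward" if d_f > d_b else "backward"
            self.trace.decision_time = self.elapsed
            self.trace.timed_out = True
        return self.decided
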
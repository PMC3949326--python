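"""Paradigm runners: predictive remapping, SSD psychometrics, ablations.

Two simulated experiments drive all results:

* **Predictive remapping** (14 deg saccade): 100 ms probe flashes at a
  variable time around the saccade, either in the present receptive field of
  a tracked LIP(CD) cell (-14 deg) or in its future receptive field (the
  fixation point).  The cell's mean rate in a 50-350 ms window after flash
  onset, plotted over flash time, yields the remapping time course; the
  response-onset lead time is the earliest flash time at which the future-
  field response exceeds 10% of the curve maximum.

* **Saccadic suppression of displacement** (8 deg saccade): the target is
  visible 500 ms before the saccade and jumps by -4..+4 deg 30 ms after
  saccade onset (or reappears displaced after a 250 ms blank).  The decision
  readout reports forward/backward; 20 seeded trials per displacement give a
  psychometric curve, summarised by an ordinary-least-squares cumulative
  Gaussian fit P(d) = 100 * Phi((d - mu) / sigma).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import ndtr

from .config import ConfigurationError, ModelConfig, config_hash
from .decision_readout import DecisionRunner, TemplateBank, build_templates
from .input_signals import cd_drive, fef_transform, retinal_drive
from .lip_circuit import AblationConfig, LipCircuit, Simulator
from .oculomotor import make_saccade, make_trajectory, schedule_events

__all__ = [
    "RemappingResult",
    "PsychometricCurve",
    "FitError",
    "select_tracked_cell",
    "run_remapping",
    "run_ssd_trial",
    "run_ssd_experiment",
    "fit_psychometric",
    "run_ablation_suite",
]


class FitError(RuntimeError):
    """Raised when the psychometric fit cannot be carried out."""


@dataclass
class RemappingResult:
    """Remapping time courses of one tracked LIP(CD) cell."""

    flash_times: np.ndarray          # ms relative to saccade onset
    frf_response: np.ndarray         # future-RF probe, mean rate in window
    rf_response: np.ndarray          # present-RF probe, gain-modulated cell
    rf_response_visual: np.ndarray   # present-RF probe, purely visual cell
    cell: tuple[int, int]            # tracked (row, column) in xb_cd
    variant: str
    onset_time: float | None = None  # ms rel. onset where FRF exceeds 10% max

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "flash_time": self.flash_times,
            "frf_response": self.frf_response,
            "rf_response_gain": self.rf_response,
            "rf_response_visual": self.rf_response_visual,
        })


@dataclass
class PsychometricCurve:
    """Displacement -> %forward table plus fitted cumulative Gaussian."""

    displacements: np.ndarray
    pct_forward: np.ndarray
    n_trials: int
    mu: float
    sigma: float
    condition: str                  # "normal" / "blank"
    ablation: str                   # "full" / "no_remap" / "no_cd" / "lateral"
    trial_records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "displacement": self.displacements,
            "pct_forward": self.pct_forward,
            "n_trials": self.n_trials,
            "condition": self.condition,
            "ablation": self.ablation,
        })

    def trials_frame(self) -> pd.DataFrame:
        """Tidy per-trial table: one row per simulated trial."""
        return pd.DataFrame(self.trial_records)


def select_tracked_cell(cfg: ModelConfig,
                        circuit: LipCircuit | None = None) -> tuple[int, int]:
    """Pick the LIP(CD) cell whose RF covers the future-field probe after the
    saccade.

    The row is the post-saccadic steady-state argmax of the visual drive for
    the probe (retinal position frf - amplitude once the eye has landed); the
    column is the argmax of the anticipatory eye-position profile at saccade
    onset, which resolves the column degeneracy of the purely visual
    steady state.
    """
    circuit = circuit or LipCircuit(cfg)
    grid = circuit.grid
    p = cfg.remap
    sacc = make_trajectory(p.amplitude, 0.0, cfg.oculomotor)
    # steady visual drive with the eye at the landing position
    post_drive = retinal_drive([(p.frf_position, 1.0)], sacc.landing, grid,
                               None, cfg)
    row = int(np.argmax(circuit.Wr @ post_drive))
    # anticipatory profile at saccade onset (envelope peak)
    cd = cd_drive(0.0, sacc, grid, cfg)
    pc = np.exp(-((grid.centers - sacc.fixation) ** 2) / cfg.signals.pc_sigma**2)
    fef = fef_transform(cd, pc, grid, cfg)
    col = int(np.argmax(circuit.Wfef @ fef))
    return row, col


def _window_mean(recorded: list[tuple[float, float]], t0: float,
                 t1: float) -> float:
    vals = [r for t, r in recorded if t0 <= t <= t1]
    return float(np.mean(vals)) if vals else 0.0


def _remap_trial(cfg: ModelConfig, circuit: LipCircuit,
                 ablation: AblationConfig, flash_time: float,
                 position: float, cell: tuple[int, int]) -> float:
    """One deterministic remapping trial; returns the window-mean response."""
    p = cfg.remap
    saccade = make_trajectory(p.amplitude, p.saccade_onset, cfg.oculomotor)
    sched = schedule_events(cfg, saccade, "remap", flash_time=flash_time,
                            flash_position=position)
    sim = Simulator(cfg, ablation, circuit)
    recorded: list[tuple[float, float]] = []
    row, col = cell

    def record(state):
        recorded.append((state.t, state.lip.xb_cd.rates[row, col]))
        return False

    sim.run(sched, callback=record)
    w0, w1 = p.window
    return _window_mean(recorded, flash_time + w0, flash_time + w1)


def run_remapping(cfg: ModelConfig, variant: str = "intermediate",
                  corollary_discharge: bool = True,
                  circuit: LipCircuit | None = None) -> RemappingResult:
    """Simulate the full remapping experiment (deterministic, no scatter).

    Produces the RF response curves for both LIP(CD) cell classes (purely
    visual and gain-modulated) and the FRF (predictive) response curve,
    each point being one trial at one flash time.
    """
    circuit = circuit or LipCircuit(cfg)
    p = cfg.remap
    flash_rel = np.arange(p.flash_from, p.flash_to + 1e-9, p.flash_step)
    if p.saccade_onset + p.flash_from < 0:
        raise ConfigurationError("earliest flash precedes simulation start")
    cell = select_tracked_cell(cfg, circuit)
    ab_gain = AblationConfig(variant=variant,
                             corollary_discharge=corollary_discharge)
    ab_vis = AblationConfig(variant=variant, gain_modulated=False,
                            corollary_discharge=corollary_discharge)
    frf, rf_gain, rf_vis = [], [], []
    for rel in flash_rel:
        t_flash = p.saccade_onset + rel
        frf.append(_remap_trial(cfg, circuit, ab_gain, t_flash,
                                p.frf_position, cell))
        rf_gain.append(_remap_trial(cfg, circuit, ab_gain, t_flash,
                                    p.rf_position, cell))
        rf_vis.append(_remap_trial(cfg, circuit, ab_vis, t_flash,
                                   p.rf_position, cell))
    result = RemappingResult(
        flash_times=flash_rel,
        frf_response=np.asarray(frf),
        rf_response=np.asarray(rf_gain),
        rf_response_visual=np.asarray(rf_vis),
        cell=cell,
        variant=variant,
    )
    result.onset_time = response_onset(result.flash_times,
                                       result.frf_response,
                                       p.onset_fraction)
    return result


def response_onset(flash_times: np.ndarray, response: np.ndarray,
                   fraction: float = 0.1) -> float | None:
    """Earliest flash time at which the response exceeds ``fraction`` of the
    curve maximum; None if the curve never does (e.g. ablated CD)."""
    peak = float(response.max())
    if peak <= 0:
        return None
    above = np.nonzero(response >= fraction * peak)[0]
    return float(flash_times[above[0]]) if above.size else None


def run_ssd_trial(cfg: ModelConfig, displacement: float,
                  rng: np.random.Generator,
                  condition: str = "normal",
                  ablation: AblationConfig | None = None,
                  circuit: LipCircuit | None = None,
                  bank: TemplateBank | None = None,
                  return_trace: bool = False):
    """One closed-loop SSD trial; returns "forward" or "backward".

    The saccade endpoint is drawn with scatter from ``rng``; the same
    generator feeds the Poisson noise of the decision stage, so a trial is
    fully reproducible from one seeded generator.
    """
    ablation = ablation or AblationConfig()
    circuit = circuit or LipCircuit(cfg)
    p = cfg.ssd
    saccade = make_saccade(p.amplitude, p.saccade_onset, cfg.oculomotor,
                           rng=rng)
    sched = schedule_events(cfg, saccade, "ssd", displacement=displacement,
                            condition=condition)
    if bank is None:
        bank = build_templates(cfg, sched.c_pre, ablation.variant, circuit)
    runner = DecisionRunner(bank, sched.c_pre, cfg, rng)
    sim = Simulator(cfg, ablation, circuit)
    dt = cfg.grid.dt

    def maybe_decide(state):
        if state.t >= sched.decision_start:
            return runner.update(circuit.decision_input(state), dt)
        return False

    sim.run(sched, callback=maybe_decide)
    if return_trace:
        return runner.trace.outcome, runner.trace
    return runner.trace.outcome


_CONDITION_TAGS = {"normal": 0, "blank": 1}


def run_ssd_experiment(cfg: ModelConfig, seed: int,
                       condition: str = "normal",
                       ablation: AblationConfig | None = None,
                       trials: int | None = None,
                       circuit: LipCircuit | None = None) -> PsychometricCurve:
    """Full SSD experiment: trials per displacement, %forward, OLS fit.

    Each trial draws its own generator from a seed sequence derived from the
    master seed, the condition and the ablation label, so runs are
    bit-reproducible and trials are independent.
    """
    ablation = ablation or AblationConfig()
    circuit = circuit or LipCircuit(cfg)
    p = cfg.ssd
    trials = trials if trials is not None else p.n_trials
    displacements = np.arange(p.displacement_min,
                              p.displacement_max + 1e-9,
                              p.displacement_step)
    # the decision border is the pre-saccadic target position; templates
    # describe the post-saccadic view (fixation at the saccade goal)
    c_pre = p.amplitude
    bank = build_templates(cfg, c_pre, ablation.variant, circuit)
    tag = zlib.crc32(f"{condition}/{ablation.label()}".encode())
    ss = np.random.SeedSequence([seed, tag])
    children = ss.spawn(len(displacements) * trials)
    pct = np.empty(len(displacements))
    records = []
    for i, d in enumerate(displacements):
        fwd = 0
        for k in range(trials):
            rng = np.random.default_rng(children[i * trials + k])
            out, trace = run_ssd_trial(cfg, float(d), rng, condition,
                                       ablation, circuit, bank,
                                       return_trace=True)
            fwd += out == "forward"
            records.append({
                "condition": condition, "ablation": ablation.label(),
                "displacement": float(d), "trial": k, "outcome": out,
                "decision_time": trace.decision_time,
                "timed_out": trace.timed_out,
            })
        pct[i] = 100.0 * fwd / trials
    mu, sigma = fit_psychometric(displacements, pct)
    return PsychometricCurve(displacements=displacements, pct_forward=pct,
                             n_trials=trials, mu=mu, sigma=sigma,
                             condition=condition, ablation=ablation.label(),
                             trial_records=records)


def fit_psychometric(displacements: np.ndarray,
                     pct_forward: np.ndarray) -> tuple[float, float]:
    """OLS fit of a cumulative Gaussian P(d) = 100 * Phi((d - mu) / sigma).

    Returns (mu, sigma) with sigma constrained positive.  Raises
    :class:`FitError` for degenerate data (fewer than four distinct
    displacements, or all responses 0% or all 100%).
    """
    d = np.asarray(displacements, dtype=float)
    y = np.asarray(pct_forward, dtype=float)
    if np.unique(d).size < 4:
        raise FitError("need at least four distinct displacements")
    if np.all(y == y[0]):
        raise FitError(
            f"degenerate psychometric data: all responses {y[0]:.0f}%"
        )

    def model(x, mu, sigma):
        return 100.0 * ndtr((x - mu) / sigma)

    # start at the interpolated 50% crossing and the 25-75% spread
    order = np.argsort(d)
    mu0 = float(np.interp(50.0, y[order], d[order],
                          left=d.min(), right=d.max()))
    sigma0 = max((d.max() - d.min()) / 4.0, 0.25)
    popt, _ = curve_fit(model, d, y, p0=(mu0, sigma0),
                        bounds=([-25.0, 1e-3], [25.0, 100.0]),
                        maxfev=20000)
    return float(popt[0]), float(popt[1])


_SUITE = {
    # name: (condition, ablation kwargs)
    "full": ("normal", {}),
    "no_remap": ("normal", {"remapping_feedback": False}),
    "no_cd": ("normal", {"corollary_discharge": False}),
    "blank": ("blank", {}),
    "lateral": ("normal", {"variant": "lateral"}),
}


def run_ablation_suite(cfg: ModelConfig, seed: int,
                       out_dir: str | Path | None = None,
                       names: list[str] | None = None,
                       trials: int | None = None,
                       include_remap: bool = True) -> dict:
    """Run the SSD condition x ablation quartet plus the lateral variant,
    and the remapping time courses for both variants.

    Returns a dict of :class:`PsychometricCurve` / :class:`RemappingResult`
    objects; when ``out_dir`` is given, writes a consolidated CSV of the
    psychometric points, a CSV of the remapping curves, and a JSON summary
    with the fitted parameters and the config hash.
    """
    circuit = LipCircuit(cfg)
    names = names or list(_SUITE)
    curves: dict[str, PsychometricCurve] = {}
    for name in names:
        condition, kwargs = _SUITE[name]
        ablation = AblationConfig(**kwargs)
        curves[name] = run_ssd_experiment(cfg, seed, condition, ablation,
                                          trials=trials, circuit=circuit)
    remaps: dict[str, RemappingResult] = {}
    if include_remap:
        for variant in ("intermediate", "lateral"):
            remaps[variant] = run_remapping(cfg, variant, circuit=circuit)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.concat([c.to_frame() for c in curves.values()],
                  ignore_index=True).to_csv(out / "ssd_psychometric.csv",
                                            index=False)
        pd.concat([c.trials_frame() for c in curves.values()],
                  ignore_index=True).to_csv(out / "ssd_trials.csv",
                                            index=False)
        if remaps:
            frames = []
            for variant, r in remaps.items():
                f = r.to_frame()
                f["variant"] = variant
                frames.append(f)
            pd.concat(frames, ignore_index=True).to_csv(
                out / "remapping_curves.csv", index=False)
        summary = {
            "config_hash": config_hash(cfg),
            "seed": seed,
            "psychometric": {
                name: {"mu": c.mu, "sigma": c.sigma,
                       "condition": c.condition, "ablation": c.ablation,
                       "n_trials": c.n_trials}
                for name, c in curves.items()
            },
            "remapping_onset": {
                variant: r.onset_time for variant, r in remaps.items()
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return {"curves": curves, "remapping": remaps}
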
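"""Shared test helpers."""

from lipstab import AblationConfig, Simulator, make_trajectory
from lipstab.oculomotor import TrialSchedule

FAR = 1e7  # parks the saccade far outside the simulated window


def fixation_state(cfg, circuit, stimulus, eye=0.0, duration=250.0,
                   ablation=None):
    """Steady state during fixation with one stimulus (no saccade)."""
    sacc = make_trajectory(8.0, FAR, cfg.oculomotor, fixation=eye)
    sched = TrialSchedule(saccade=sacc,
                          segments=[(0.0, duration + 1, stimulus, 1.0)],
                          t_end=duration)
    sim = Simulator(cfg, ablation or AblationConfig(), circuit)
    return sim.run(sched)
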
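"""The LIP circuit: gain-field maps, head-centered cells, remapping loop.

Two 2-D maps of n x n cells represent the two LIP populations:

* ``xb_pc`` (LIP(PC)): rows encode retinotopic stimulus position, columns the
  proprioceptive eye position; the drive is the product of the two kernelled
  input bumps, so a single activity hill emerges at their intersection.
* ``xb_cd`` (LIP(CD)): rows encode retinotopic stimulus position, columns the
  anticipated post-saccadic eye position.  Cells respond to visual input even
  without a corollary discharge, drive = xr * (1 + gain * fef); around the
  saccade the anticipatory signal both raises the gain of the column tuned to
  the future eye position and gates the remapping feedback, which injects the
  head-centered activity back along the diagonals: + k_fb * xh(l+m) * fef(m).

A population of 2n-1 head-centered cells ``xh`` collects activity along the
diagonals of both maps with the printed Gaussian readout kernels
(sigma = 15 index units, K = 0.035 from LIP(PC) and K = 0.02 from LIP(CD)).
The loop xb_cd -> xh -> xb_cd stabilises the pre-saccadic stimulus
representation across the saccade; in the lateral model variant the diagonal
input to LIP(CD) comes directly from LIP(PC) with no intermediate state and
therefore no recurrent loop.

All updates are synchronous: every drive is computed from the previous
state, then all populations take one Euler step together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigurationError, ModelConfig, config_hash
from .grid_dynamics import (RatePopulation, SpatialGrid, diagonal_kernel,
                            gaussian_kernel, make_grid)
from .input_signals import cd_drive, fef_transform, pc_eye_drive, retinal_drive
from .oculomotor import TrialSchedule

__all__ = [
    "AblationConfig",
    "LipState",
    "ModelState",
    "LipCircuit",
    "Simulator",
    "save_snapshots",
]


@dataclass(frozen=True)
class AblationConfig:
    """Switches selecting the model variant and its lesions.

    ``remapping_feedback`` disables the diagonal feedback into LIP(CD)
    (the no-remapping model); ``corollary_discharge`` disables the CD input
    globally (the no-CD model, which leaves the feedback without its
    multiplicative gate and therefore inactive as well);
    ``gain_modulated`` selects between the visual cell with pre-saccadic
    gain increase and the purely visual cell class (feedforward gain term
    off); ``variant`` picks the intermediate-cell or the lateral-connection
    implementation of the diagonal communication.
    """

    remapping_feedback: bool = True
    corollary_discharge: bool = True
    gain_modulated: bool = True
    variant: str = "intermediate"

    def __post_init__(self) -> None:
        if self.variant not in ("intermediate", "lateral"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")

    def label(self) -> str:
        if self.variant == "lateral":
            return "lateral"
        if not self.corollary_discharge:
            return "no_cd"
        if not self.remapping_feedback:
            return "no_remap"
        return "full"


@dataclass
class LipState:
    """The three LIP populations at one simulation time step."""

    xb_pc: RatePopulation   # (n, n) retinal x registered eye position
    xb_cd: RatePopulation   # (n, n) retinal x anticipated eye position
    xh: RatePopulation      # (2n-1,) head-centered diagonal bins


@dataclass
class ModelState:
    """All coupled populations plus the ablation switches at one time step."""

    xr: RatePopulation
    xe_pc: RatePopulation
    xe_cd: RatePopulation
    lip: LipState
    fef: np.ndarray
    ablation: AblationConfig
    t: float = 0.0


class LipCircuit:
    """Precomputed connectivity and drive terms of the LIP model.

    Holds the shared grid, the feedforward input kernels, the diagonal
    readout kernels, and the diagonal index table; all drive computations
    are pure functions of population rate vectors.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.grid: SpatialGrid = make_grid(cfg.grid.n, cfg.grid.v)
        n = self.grid.n
        sig = cfg.lip.input_sigma
        self.Wr = gaussian_kernel(self.grid, self.grid, 1.0, sig,
                                  "horizontal", normalize=True).matrix
        self.Wpc = gaussian_kernel(self.grid, self.grid, 1.0, sig,
                                   "vertical", normalize=True).matrix
        self.Wfef = gaussian_kernel(self.grid, self.grid, 1.0, sig,
                                    "vertical", normalize=True).matrix
        self.Wd_pc = diagonal_kernel(n, cfg.lip.k_diag_pc, cfg.lip.diag_sigma).matrix
        self.Wd_cd = diagonal_kernel(n, cfg.lip.k_diag_cd, cfg.lip.diag_sigma).matrix
        # l + m for every 2-D cell: index into the head-centered bins
        self.diag_index = np.add.outer(np.arange(n), np.arange(n))
        self.n_diag = 2 * n - 1
        # head-centered position encoded by each diagonal bin
        self.diag_positions = -cfg.grid.v + np.arange(self.n_diag) * self.grid.spacing

    # ---- drive terms (all computed from previous-state rates) ----

    def drive_xb_pc(self, xr: np.ndarray, xe_pc: np.ndarray) -> np.ndarray:
        """Gain-field drive: kernelled retinal input x kernelled eye position."""
        return self.cfg.lip.gain_pc * np.outer(self.Wr @ xr, self.Wpc @ xe_pc)

    def drive_xb_cd(self, xr: np.ndarray, xe_fef: np.ndarray,
                    xh: np.ndarray, ablation: AblationConfig) -> np.ndarray:
        """LIP(CD) drive: gain-modulated visual term plus remapping feedback."""
        rows = self.Wr @ xr
        cols = self.Wfef @ xe_fef
        if ablation.gain_modulated:
            drive = np.outer(rows, 1.0 + self.cfg.lip.gain_ff * cols)
        else:
            drive = np.repeat(rows[:, None], self.grid.n, axis=1)
        if ablation.remapping_feedback and ablation.corollary_discharge:
            # bounded synaptic transfer: linear at operating amplitudes,
            # saturating above, so the recurrent xb_cd -> xh -> xb_cd loop
            # stabilises the pre-saccadic trace without running away while
            # the CD envelope is high
            x0 = self.cfg.lip.fb_sat
            drive += (self.cfg.lip.k_fb * x0
                      * np.tanh(xh[self.diag_index] / x0) * cols[None, :])
        return drive

    def drive_xh(self, xb_pc: np.ndarray, xb_cd: np.ndarray) -> np.ndarray:
        """Head-centered drive: Gaussian-weighted diagonal sums of both maps."""
        if xb_pc.shape != xb_cd.shape:
            raise ValueError("xb_pc and xb_cd must have the same shape")
        return self.Wd_pc @ xb_pc.ravel() + self.Wd_cd @ xb_cd.ravel()

    def lateral_variant_drive(self, xb_pc: np.ndarray, xe_fef: np.ndarray,
                              ablation: AblationConfig,
                              xr: np.ndarray) -> np.ndarray:
        """LIP(CD) drive for the lateral variant: the diagonal input comes
        directly from the LIP(PC) diagonal sums, with no intermediate state
        and hence no recurrent loop."""
        if ablation.variant != "lateral":
            raise ValueError("lateral_variant_drive requires variant='lateral'")
        rows = self.Wr @ xr
        cols = self.Wfef @ xe_fef
        if ablation.gain_modulated:
            drive = np.outer(rows, 1.0 + self.cfg.lip.gain_ff * cols)
        else:
            drive = np.repeat(rows[:, None], self.grid.n, axis=1)
        if ablation.remapping_feedback and ablation.corollary_discharge:
            dsum = self.Wd_pc @ xb_pc.ravel()
            x0 = self.cfg.lip.fb_sat
            drive += (self.cfg.lip.k_fb * x0
                      * np.tanh(dsum[self.diag_index] / x0) * cols[None, :])
        return drive

    def decision_input(self, state: ModelState) -> np.ndarray:
        """Input to the decision process over the 2n-1 head-centered bins.

        Intermediate variant: the head-centered rates themselves (identity).
        Lateral variant: the printed Gaussian diagonal readout of both LIP
        maps.
        """
        if state.ablation.variant == "intermediate":
            return state.lip.xh.rates
        return (self.Wd_pc @ state.lip.xb_pc.rates.ravel()
                + self.Wd_cd @ state.lip.xb_cd.rates.ravel())

    # ---- synchronous step ----

    def step_lip(self, state: ModelState, xr_kernel_input: np.ndarray,
                 dt: float) -> None:
        """One synchronous Euler update of xb_pc, xb_cd, xh in place.

        All drives are evaluated on the previous-state rates before any
        population is advanced.
        """
        lip = state.lip
        d_pc = self.drive_xb_pc(xr_kernel_input, state.xe_pc.rates)
        if state.ablation.variant == "lateral":
            d_cd = self.lateral_variant_drive(lip.xb_pc.rates, state.fef,
                                              state.ablation, xr_kernel_input)
            lip.xb_pc.step(d_pc, dt)
            lip.xb_cd.step(d_cd, dt)
        else:
            d_cd = self.drive_xb_cd(xr_kernel_input, state.fef,
                                    lip.xh.rates, state.ablation)
            d_h = self.drive_xh(lip.xb_pc.rates, lip.xb_cd.rates)
            lip.xb_pc.step(d_pc, dt)
            lip.xb_cd.step(d_cd, dt)
            lip.xh.step(d_h, dt)


class Simulator:
    """Closed-loop trial simulator coupling inputs, saccade, and LIP."""

    def __init__(self, cfg: ModelConfig, ablation: AblationConfig | None = None,
                 circuit: LipCircuit | None = None):
        self.cfg = cfg
        self.ablation = ablation or AblationConfig()
        self.circuit = circuit or LipCircuit(cfg)
        self.state: ModelState | None = None
        self.schedule: TrialSchedule | None = None

    def reset(self, schedule: TrialSchedule) -> ModelState:
        cfg, grid = self.cfg, self.circuit.grid
        tau = cfg.grid.tau_map
        diag_grid = make_grid(self.circuit.n_diag, 2 * cfg.grid.v)
        lip = LipState(
            xb_pc=RatePopulation.zeros(grid, tau, grid2=grid),
            xb_cd=RatePopulation.zeros(grid, tau, grid2=grid),
            xh=RatePopulation.zeros(diag_grid, tau),
        )
        self.state = ModelState(
            xr=RatePopulation.zeros(grid, tau),
            xe_pc=RatePopulation.zeros(grid, tau),
            xe_cd=RatePopulation.zeros(grid, tau),
            lip=lip,
            fef=np.zeros(grid.n),
            ablation=self.ablation,
            t=0.0,
        )
        self.schedule = schedule
        return self.state

    def step(self) -> ModelState:
        """Advance the whole model by one Euler step (synchronous update)."""
        assert self.state is not None and self.schedule is not None
        cfg, grid, state = self.cfg, self.circuit.grid, self.state
        sched = self.schedule
        t, dt = state.t, cfg.grid.dt
        saccade = sched.saccade

        # anticipatory eye position from the previous CD / PC rates
        if self.ablation.corollary_discharge:
            state.fef = fef_transform(state.xe_cd.rates, state.xe_pc.rates,
                                      grid, cfg)
        # LIP update from previous-state rates
        self.circuit.step_lip(state, state.xr.rates, dt)

        # input maps
        eye = saccade.eye_position(t)
        fb = state.lip.xb_pc.rates.sum(axis=1)
        d_xr = retinal_drive(sched.stimuli_at(t), eye, grid, fb, cfg)
        d_pc = pc_eye_drive(t, saccade, grid, cfg)
        d_cd = cd_drive(t, saccade, grid, cfg,
                        enabled=self.ablation.corollary_discharge)
        state.xr.step(d_xr, dt)
        state.xe_pc.step(d_pc, dt)
        state.xe_cd.step(d_cd, dt)
        state.t = t + dt
        return state

    def run(self, schedule: TrialSchedule, until: float | None = None,
            callback=None) -> ModelState:
        """Run a full trial; ``callback(state)`` fires after every step and
        may return True to stop early."""
        state = self.reset(schedule)
        t_end = schedule.t_end if until is None else until
        while state.t < t_end:
            self.step()
            if callback is not None and callback(state):
                break
        return state


def save_snapshots(states: list[tuple[float, ModelState]], out_dir: str | Path,
                   cfg: ModelConfig, seed: int | None = None) -> None:
    """Export map snapshots as CSV matrices plus a long-format table.

    One ``<map>_t<ms>.csv`` per requested time and map, a combined
    ``snapshots_long.csv`` with columns (t, map, i, j, rate) for animation,
    and a ``run_meta.json`` with the config hash, seed and ablation flags.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for t, state in states:
        maps = {
            "xr": state.xr.rates[None, :],
            "xe_pc": state.xe_pc.rates[None, :],
            "xe_cd": state.xe_cd.rates[None, :],
            "xe_fef": state.fef[None, :],
            "xb_pc": state.lip.xb_pc.rates,
            "xb_cd": state.lip.xb_cd.rates,
            "xh": state.lip.xh.rates[None, :],
        }
        for name, mat in maps.items():
            np.savetxt(out / f"{name}_t{int(round(t))}.csv", mat, delimiter=",")
            ii, jj = np.nonzero(np.ones_like(mat))
            rows.append(pd.DataFrame({
                "t": t, "map": name, "i": ii, "j": jj,
                "rate": mat[ii, jj],
            }))
    pd.concat(rows, ignore_index=True).to_csv(out / "snapshots_long.csv",
                                              index=False)
    ab = states[-1][1].ablation
    meta = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "ablation": {
            "remapping_feedback": ab.remapping_feedback,
            "corollary_discharge": ab.corollary_discharge,
            "gain_modulated": ab.gain_modulated,
            "variant": ab.variant,
        },
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
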
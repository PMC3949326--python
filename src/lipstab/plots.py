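"""Figure-style plots of remapping time courses and SSD psychometrics."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
from scipy.special import ndtr

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from .experiments import PsychometricCurve, RemappingResult  # noqa: E402

__all__ = ["plot_remapping", "plot_psychometric"]


def plot_remapping(result: RemappingResult, path: str | Path) -> None:
    """Remapping time courses: RF responses of both cell classes and the
    predictive FRF response, aligned to saccade onset."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    t = result.flash_times
    ax1.plot(t, result.rf_response_visual, color="tab:green",
             label="purely visual cell")
    ax1.plot(t, result.rf_response, color="tab:red", ls="--",
             label="gain-modulated cell")
    ax1.set_title("stimulus in RF")
    ax1.legend(frameon=False, fontsize=8)
    ax2.plot(t, result.frf_response, color="tab:blue")
    ax2.set_title("stimulus in future RF")
    if result.onset_time is not None:
        ax2.axvline(result.onset_time, color="gray", ls=":",
                    label=f"onset {result.onset_time:.0f} ms")
        ax2.legend(frameon=False, fontsize=8)
    for ax in (ax1, ax2):
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_xlabel("flash time rel. saccade onset (ms)")
        ax.set_ylabel("mean rate, 50-350 ms window")
    fig.suptitle(f"{result.variant} variant, cell {result.cell}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_psychometric(curves: dict[str, PsychometricCurve],
                      path: str | Path) -> None:
    """Psychometric curves (%forward vs displacement) with their fitted
    cumulative Gaussians, one panel per condition."""
    names = list(curves)
    fig, axes = plt.subplots(1, len(names), figsize=(3.2 * len(names), 3.2),
                             sharey=True)
    axes = np.atleast_1d(axes)
    grid = np.linspace(-4.5, 4.5, 200)
    for ax, name in zip(axes, names):
        c = curves[name]
        ax.plot(c.displacements, c.pct_forward, "+", color="tab:blue", ms=8)
        ax.plot(grid, 100.0 * ndtr((grid - c.mu) / c.sigma), "k-", lw=1)
        ax.axhline(50, color="gray", lw=0.5, ls=":")
        ax.set_title(f"{name}\nmu={c.mu:+.2f}, sigma={c.sigma:.2f}",
                     fontsize=9)
        ax.set_xlabel("displacement (deg)")
    axes[0].set_ylabel("% forward reports")
    axes[0].set_ylim(-5, 105)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
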
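"""Matplotlib helpers for bifurcation diagrams and critical-noise curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt

from .sweeps import SweepResult


def plot_bifurcation(sweeps: dict, ax=None, title: str | None = None):
    """Run-averaged stationary polarization vs noise, one curve per key
    (typically the topology parameter p)."""
    if ax is None:
        _, ax = plt.subplots()
    for label, sweep in sweeps.items():
        etas, mp = sweep.mean_psi()
        ax.plot(etas, mp, "o-", label=str(label))
    ax.set_xlabel(r"noise intensity $\eta$")
    ax.set_ylabel(r"polarization $\psi$")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax


def plot_eta_c_curve(table, x="p", ax=None, title: str | None = None):
    """Critical noise vs a control parameter (p or b)."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(table[x], table["eta_c"], "s-")
    ax.set_xlabel(x)
    ax.set_ylabel(r"critical noise $\eta_c$")
    if title:
        ax.set_title(title)
    return ax
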
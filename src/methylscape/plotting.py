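"""Diagnostic plots for fit and reweighting results.

Matplotlib is imported lazily so headless pipelines never pay for it.
Each function accepts an optional ``ax`` and returns the axes it drew on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "plot_relaxation_fit",
    "plot_lcurve",
    "plot_tcf",
    "plot_delta_entropy",
]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_relaxation_fit(results, n_curves: int = 100, seed: int = 0, ax=None):
    """Observed 3Q/SQ ratio with posterior ratio curves overlaid."""
    ax = _get_ax(ax)
    model = results.model
    if model is None:
        raise ValueError("results are detached from their model")
    from .relaxation import intensity_ratio

    t = model.delays
    ax.plot(t * 1e3, model.tq / model.sq, "o", label="data", zorder=3)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(results.samples), size=n_curves)
    grid = np.linspace(t[0], t[-1], 100)
    for i in idx:
        row = results.samples.iloc[i]
        ax.plot(
            grid * 1e3,
            intensity_ratio(row["eta"], row["delta"], grid),
            color="k",
            alpha=0.05,
            lw=0.8,
        )
    ax.set_xlabel("relaxation delay T (ms)")
    ax.set_ylabel("I3Q / ISQ")
    ax.set_title(f"{results.peak_id}: posterior build-up curves")
    return ax


def plot_lcurve(lcurve, ax=None):
    """χ² and Neff against θ; the selected elbow is marked."""
    ax = _get_ax(ax)
    ax.loglog(lcurve.theta, np.maximum(lcurve.chi2, 1e-12), "o-", label="chi-squared")
    ax.set_xlabel("theta")
    ax.set_ylabel("chi-squared")
    ax2 = ax.twinx()
    ax2.semilogx(lcurve.theta, lcurve.neff, "s--", color="tab:green", label="Neff")
    ax2.set_ylabel("Neff")
    ax2.set_ylim(0, 1.05)
    if lcurve.selected_theta is not None:
        ax.axvline(lcurve.selected_theta, color="tab:red", ls=":", label="selected theta")
    ax.legend(loc="upper left")
    return ax


def plot_tcf(tcf, ax=None):
    """Internal TCF with per-replica curves (grey) and their average."""
    ax = _get_ax(ax)
    for rep in tcf.replicas:
        ax.plot(tcf.lags, rep, color="0.6", lw=0.8)
    ax.plot(tcf.lags, tcf.values, color="tab:green", lw=2, label="average")
    ax.set_xlabel("lag (frames)")
    ax.set_ylabel("C_int")
    ax.set_ylim(-0.55, 1.05)
    ax.legend()
    return ax


def plot_delta_entropy(ds, ax=None):
    """Per-residue ΔS bar map between two ligand states."""
    ax = _get_ax(ax)
    ax.bar(np.arange(len(ds)), ds["delta_s"].to_numpy())
    ax.set_xticks(np.arange(len(ds)))
    ax.set_xticklabels(ds.index, rotation=90, fontsize=8)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("dS_SC (dimensionless)")
    a = ds.attrs.get("state_a", "a")
    b = ds.attrs.get("state_b", "b")
    ax.set_title(f"side-chain entropy change: {b} - {a}")
    return ax
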
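"""Figures for the stage analysis: group means and structure-function."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .cohort import STAGES


def stage_plot(df: pd.DataFrame, parameter: str, ax=None,
               stage_col: str = "stage"):
    """Per-stage scatter with mean and 95% CI error bars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    stages = [s for s in STAGES if s in set(df[stage_col])]
    for i, st in enumerate(stages):
        vals = df.loc[df[stage_col] == st, parameter].dropna()
        ax.plot(np.full(len(vals), i) + np.random.default_rng(0).uniform(
            -0.08, 0.08, len(vals)), vals, ".", color="0.7", ms=4)
        m = vals.mean()
        ci = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0
        ax.errorbar([i], [m], yerr=[ci], fmt="o", color="k", capsize=3)
    ax.set_xticks(range(len(stages)), stages)
    ax.set_xlabel("stage")
    ax.set_ylabel(parameter)
    return ax


def structure_function_plot(df: pd.DataFrame, parameter: str, ax=None,
                            vfmd_col: str = "vfmd_db"):
    """Parameter vs VF MD scatter with least-squares line and Pearson r."""
    from scipy import stats as sps

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    sub = df[[vfmd_col, parameter]].dropna()
    x, y = sub[vfmd_col].to_numpy(), sub[parameter].to_numpy()
    ax.plot(x, y, ".", color="0.6", ms=4)
    if len(sub) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
        res = sps.linregress(x, y)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, res.intercept + res.slope * xs, "b-")
        ax.annotate(f"r = {res.rvalue:.2f}", xy=(0.05, 0.9),
                    xycoords="axes fraction", color="red")
    ax.set_xlabel("VF MD (dB)")
    ax.set_ylabel(parameter)
    return ax


def save_analysis_figures(df: pd.DataFrame, parameters: list[str],
                          outdir) -> list:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in parameters:
        fig, axes = plt.subplots(1, 2, figsize=(8, 3))
        stage_plot(df, p, ax=axes[0])
        structure_function_plot(df, p, ax=axes[1])
        fig.tight_layout()
        path = outdir / f"{p}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)
    return paths
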
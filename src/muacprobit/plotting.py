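"""Bias / precision vs sample size plots from a metrics grid (matplotlib)."""

from __future__ import annotations

import pandas as pd

_STYLES = {"classic": "o-", "probit_I": "s--", "probit_II": "^:"}


def _plot_metric(metrics: pd.DataFrame, column: str, ylabel: str, cutoff_mm: float, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = metrics[metrics["cutoff_mm"] == cutoff_mm]
    for method, grp in sub.groupby("method"):
        grp = grp.sort_values("sample_size")
        ax.plot(grp["sample_size"], grp[column], _STYLES.get(method, "-"), label=method)
    ax.set_xlabel("sample size")
    ax.set_ylabel(ylabel)
    ax.set_title(f"cutoff {cutoff_mm:g} mm")
    ax.legend()
    return ax


def plot_bias(metrics: pd.DataFrame, cutoff_mm: float = 125.0, ax=None):
    """Mean bias (pp) against sample size, one line per method."""
    ax = _plot_metric(metrics, "bias_pp", "mean bias (pp)", cutoff_mm, ax)
    ax.axhline(0.0, color="grey", lw=0.8)
    return ax


def plot_precision(metrics: pd.DataFrame, cutoff_mm: float = 125.0, ax=None):
    """Mean CI half-width (pp) against sample size, one line per method."""
    return _plot_metric(metrics, "precision_pp", "mean CI half-width (pp)", cutoff_mm, ax)


def plot_coverage(metrics: pd.DataFrame, cutoff_mm: float = 125.0, ax=None):
    """Empirical coverage against sample size with the nominal 0.95 line."""
    ax = _plot_metric(metrics, "coverage", "coverage of 95% CI", cutoff_mm, ax)
    ax.axhline(0.95, color="grey", lw=0.8, ls="--")
    return ax
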
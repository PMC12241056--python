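"""Figures: per-tract loading bars with bootstrap CI whiskers, and the
expression-vs-fitness scatter."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt


def plot_loadings(tract_labels, loadings, reliability=None, ax=None, title=None):
    """Bar chart of tract loadings with 95% CI whiskers and significance
    asterisks (tracts whose CI excludes zero)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(max(8, 0.25 * len(tract_labels)), 4))
    x = np.arange(len(tract_labels))
    ax.bar(x, loadings, color="#3b6fb6", width=0.7, label="loading")
    if reliability is not None:
        lo, hi = reliability.ci_lower, reliability.ci_upper
        yerr = np.vstack([np.asarray(loadings) - lo, hi - np.asarray(loadings)])
        yerr = np.clip(yerr, 0, None)  # percentile CI need not bracket the point
        ax.errorbar(x, loadings, yerr=yerr, fmt="none", ecolor="#c0392b",
                    elinewidth=1.2, capsize=2, label="95% CI")
        span = max(float(np.max(np.abs(hi))), float(np.max(np.abs(lo))), 1e-12)
        for xi, sig, h, l in zip(x, reliability.significant, hi, lo):
            if sig:
                ax.text(xi, max(h, 0) + 0.04 * span, "*",
                        ha="center", va="bottom", fontsize=11)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_xticks(x)
    ax.set_xticklabels(tract_labels, rotation=90, fontsize=7)
    ax.set_ylabel("pattern loading")
    if title:
        ax.set_title(title)
    ax.figure.tight_layout()
    return ax


def plot_expression_scatter(expression, vo2max, adjusted_r2=None, p_value=None,
                            ax=None, title=None):
    """Pattern expression against VO2max with the fitted line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    e = np.asarray(expression, dtype=float)
    y = np.asarray(vo2max, dtype=float)
    ax.scatter(e, y, s=18, color="#3b6fb6", alpha=0.7)
    slope, intercept = np.polyfit(e, y, 1)
    xs = np.linspace(e.min(), e.max(), 50)
    ax.plot(xs, intercept + slope * xs, color="#c0392b", linewidth=1.5)
    label = []
    if adjusted_r2 is not None:
        label.append(f"adj. $R^2$ = {adjusted_r2:.3f}")
    if p_value is not None:
        label.append(f"p = {p_value:.2e}")
    if label:
        ax.annotate("\n".join(label), xy=(0.03, 0.95), xycoords="axes fraction",
                    va="top", fontsize=9)
    ax.set_xlabel("pattern expression (z)")
    ax.set_ylabel("VO2max (ml/kg/min)")
    if title:
        ax.set_title(title)
    ax.figure.tight_layout()
    return ax
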
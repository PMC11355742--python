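"""Matplotlib views of attribution and benchmark results."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")  # headless backend; callers can switch before import
import matplotlib.pyplot as plt  # noqa: E402


def plot_importance(ranking, top: int = 20, ax=None):
    """Horizontal bar chart of normalized feature importances."""
    tab = ranking.table.head(top)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(tab) + 1))
    ax.barh(tab.index[::-1], tab["importance"][::-1], color="#3b6fb6")
    ax.set_xlabel("normalized mean |attribution|")
    ax.set_title("Feature importance")
    ax.figure.tight_layout()
    return ax


def plot_summary(summary_frame, top: int = 15, ax=None, rng_seed: int = 0):
    """Beeswarm-style summary: one jittered row per feature, colored by value."""
    feats = list(dict.fromkeys(summary_frame["feature"]))[:top]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.35 * len(feats) + 1))
    rng = np.random.default_rng(rng_seed)
    for i, f in enumerate(reversed(feats)):
        sub = summary_frame[summary_frame["feature"] == f]
        v = sub["feature_value"].to_numpy(dtype=float)
        span = np.ptp(v)
        color = (v - v.min()) / span if span > 0 else np.full(len(v), 0.5)
        ax.scatter(sub["attribution"], i + rng.normal(0, 0.07, len(sub)),
                   c=color, cmap="coolwarm", s=8, alpha=0.8)
    ax.set_yticks(range(len(feats)), list(reversed(feats)))
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("attribution (positive-class probability)")
    ax.figure.tight_layout()
    return ax


def plot_waterfall(wf, top: int = 12, ax=None):
    """Signed contribution bars from the base value to the final output."""
    entries = wf.entries[:top]
    rest = sum(e.contribution for e in wf.entries[top:])
    labels = [f"{e.feature} = {e.value}" for e in entries]
    vals = [e.contribution for e in entries]
    if rest:
        labels.append("remaining features")
        vals.append(rest)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * len(vals) + 1.2))
    colors = ["#c0392b" if v > 0 else "#2e6da4" for v in vals]
    ax.barh(range(len(vals))[::-1], vals, color=colors)
    ax.set_yticks(range(len(vals))[::-1], labels)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_title(f"subject {wf.subject_id}: base {wf.base_value:.3f} "
                 f"-> final {wf.final_value:.3f}")
    ax.set_xlabel("contribution")
    ax.figure.tight_layout()
    return ax


def plot_win_probability(win_table, ax=None):
    """Win probability with bootstrap error bars, one point per model."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    tab = win_table.sort_values("win_probability")
    ax.errorbar(tab["win_probability"], range(len(tab)),
                xerr=tab["uncertainty"], fmt="o", color="#3b6fb6")
    ax.set_yticks(range(len(tab)), tab.index)
    ax.set_xlabel("probability of winning")
    ax.figure.tight_layout()
    return ax


def plot_accuracy_density(densities, ax=None):
    """Overlaid accuracy densities for every benchmarked model."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for name, d in densities.items():
        if d["degenerate"] or d["density"] is None:
            ax.axvline(d["mode"], ls="--", label=f"{name} (degenerate)")
        else:
            ax.plot(d["grid"], d["density"], label=name)
    ax.set_xlabel("accuracy")
    ax.set_ylabel("density")
    ax.set_xlim(0.4, 1.0)
    ax.legend(fontsize=7)
    ax.figure.tight_layout()
    return ax
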
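"""Minimal forest-plot helper for hazard-ratio tables."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt


def forest_plot(results_table, ax=None):
    """HRs with 95% CIs on a log axis, one row per (outcome, care_setting)."""
    df = results_table
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1.2))
    labels = [f"{r.outcome} [{r.care_setting}]" if r.care_setting != "all"
              else str(r.outcome) for r in df.itertuples()]
    y = range(len(df))[::-1]
    ax.errorbar(df["hr"], list(y), fmt="s", color="k", markersize=4,
                xerr=[df["hr"] - df["ci_low"], df["ci_high"] - df["hr"]],
                ecolor="gray", capsize=2, linestyle="none")
    ax.axvline(1.0, color="r", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_yticks(list(y))
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("hazard ratio (95% CI)")
    ax.figure.tight_layout()
    return ax
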
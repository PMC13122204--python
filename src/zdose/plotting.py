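"""Cluster plot of a genotyped cohort (ddCq strip + box summaries)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from zdose.genotyping import CohortResult, SexCall
from zdose.stats import box_summary

_COLORS = {SexCall.MALE: "#2a6fba", SexCall.FEMALE: "#c23b3b", SexCall.REPEAT: "#888888"}


def cluster_plot(result: CohortResult, path: str | Path | None = None):
    """One-panel ddCq plot: jittered points per call plus box summaries.

    Males sit near ddCq = 0 and females near -1; the dashed line marks the
    classification threshold.
    """
    fig, ax = plt.subplots(figsize=(4, 4))
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    groups = {
        SexCall.MALE: [s.ddcq for s in result.samples if s.call is SexCall.MALE],
        SexCall.FEMALE: [s.ddcq for s in result.samples if s.call is SexCall.FEMALE],
        SexCall.REPEAT: [s.ddcq for s in result.samples if s.call is SexCall.REPEAT],
    }
    positions = {SexCall.MALE: 1.0, SexCall.FEMALE: 2.0, SexCall.REPEAT: 3.0}
    for call, values in groups.items():
        if not values:
            continue
        x0 = positions[call]
        xs = x0 + rng.uniform(-0.08, 0.08, size=len(values))
        ax.scatter(xs, values, s=18, color=_COLORS[call], zorder=3, label=call.value)
        if len(values) >= 2:
            b = box_summary(values)
            ax.hlines([b.q1, b.median, b.q3], x0 - 0.18, x0 + 0.18, color="k", lw=1)
            ax.vlines([x0 - 0.18, x0 + 0.18], b.q1, b.q3, color="k", lw=1)
            ax.vlines(x0, b.whisker_lo, b.q1, color="k", lw=1)
            ax.vlines(x0, b.q3, b.whisker_hi, color="k", lw=1)
    ax.axhline(result.threshold, ls="--", color="0.4", lw=1)
    ax.set_xticks(
        [positions[c] for c in groups if groups[c]],
        [c.value for c in groups if groups[c]],
    )
    ax.set_ylabel(r"$\Delta\Delta C_q$ (cycles)")
    ax.set_xlim(0.5, 3.5)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
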
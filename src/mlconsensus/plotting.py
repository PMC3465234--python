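"""AUC-versus-scope charts with plateau markers.

Renders the standard diagnostic view of a scope track: sum-of-TPR AUC on
the y-axis, the ordered scope settings (no PS, 1..10, full) on the x-axis,
small diamonds on plateau scopes, a round marker on the AUC peak, and a
large diamond when the peak lies inside the plateau.
"""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .evaluation import PlateauReport


def _scope_label(scope) -> str:
    return "none" if scope is None else str(scope)


def plot_auc_vs_scope(
    tracks: Mapping[str, PlateauReport],
    *,
    title: str | None = None,
    ax=None,
):
    """Plot one curve per named track (e.g. ``{"IC": report, "no IC": ...}``)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for name, report in tracks.items():
        xs = list(range(len(report.scopes)))
        ys = [report.aucs[s] for s in report.scopes]
        (line,) = ax.plot(xs, ys, marker=".", label=name)
        color = line.get_color()
        for i, scope in enumerate(report.scopes):
            if scope in report.plateau:
                ax.plot(i, ys[i], marker="D", ms=6, color=color, mfc="none")
        peak = report.scopes.index(report.max_auc_scope)
        ax.plot(peak, ys[peak], marker="o", ms=9, color=color, mfc="none")
        if report.peak_in_plateau:
            ax.plot(peak, ys[peak], marker="D", ms=12, color=color, mfc="none")
        ax.set_xticks(xs, [_scope_label(s) for s in report.scopes])
    ax.set_xlabel("pairwise-score scope")
    ax.set_ylabel("AUC (sum of per-slot TPR)")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax
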
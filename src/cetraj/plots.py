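"""Marginal trajectory figures (predicted score vs. years from the origin)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_trajectories(analysis: dict, group_label: str, path) -> None:
    """Plot per-domain marginal trajectories for one matched analysis.

    ``analysis`` is the per-group block of a run summary (the output of
    :func:`cetraj.pipeline.analyse_matched_group`); one panel per outcome,
    exposed and control curves over the contrast window.
    """
    outcomes = analysis["outcomes"]
    fig, axes = plt.subplots(1, len(outcomes), figsize=(5.2 * len(outcomes), 3.6), squeeze=False)
    for ax, (outcome, res) in zip(axes[0], outcomes.items()):
        tr = res["trajectory"]
        ax.plot(tr["times"], tr["exposed"], label="continuing education", color="#c23b22")
        ax.plot(tr["times"], tr["control"], label="control", color="#1f77b4", linestyle="--")
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("years from first CE report (t)")
        ax.set_ylabel(f"{outcome} (SD units)")
        ax.set_title(f"{group_label}: {outcome}")
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
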
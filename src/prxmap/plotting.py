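"""Minimal UpSet-style rendering of exclusive intersection counts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .sets import IntersectionTable


def plot_intersections(table: IntersectionTable, path) -> None:
    """Bar chart of exclusive membership-pattern counts (matrix layout)."""
    frame = table.to_frame()
    frame = frame.sort_values("count", ascending=False)
    names = list(table.set_names)
    fig, (ax_bar, ax_mat) = plt.subplots(
        2, 1, figsize=(max(6, 0.5 * len(frame)), 5),
        gridspec_kw={"height_ratios": [3, 1]}, sharex=True,
    )
    x = range(len(frame))
    ax_bar.bar(x, frame["count"], color="0.25")
    ax_bar.set_ylabel("exclusive intersection size")
    for xi, pattern in zip(x, frame["pattern"]):
        members = set(pattern.split("&"))
        for yi, name in enumerate(names):
            filled = name in members
            ax_mat.plot(xi, yi, "o", color="0.15" if filled else "0.85", ms=6)
    ax_mat.set_yticks(range(len(names)), names)
    ax_mat.set_xticks([])
    ax_mat.set_ylim(-0.5, len(names) - 0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
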
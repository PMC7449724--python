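"""Optional figure rendering (PNG side-effects; canonical outputs are the
machine-readable tables)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .imaging import NormalizedImage
from .stats import GroupSummary, StatReport


def _axes(figsize):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=figsize)


def save_image_heatmap(img: NormalizedImage, path, vmax: float | None = None):
    """Diverging heatmap of a normalized |M| image, ROI outlined."""
    from matplotlib.patches import Rectangle

    fig, ax = _axes((5, 4))
    v = vmax if vmax is not None else max(np.max(np.abs(img.grid)), 1e-6)
    h = ax.imshow(img.grid, cmap="RdBu", vmin=-v, vmax=v, origin="upper")
    ri, rj = img.roi
    ax.add_patch(
        Rectangle(
            (rj.start - 0.5, ri.start - 0.5),
            rj.stop - rj.start,
            ri.stop - ri.start,
            fill=False,
            edgecolor="k",
            linewidth=1,
        )
    )
    fig.colorbar(h, ax=ax, label=r"$|M|_{norm}$")
    ax.set_title(f"normalized |M| at {img.f_eval} THz")
    fig.savefig(Path(path), dpi=150, bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(fig)
    return Path(path)


def save_tukey_bar(
    groups: Sequence[GroupSummary], report: StatReport, path
):
    """Group means with Tukey minimal-significant-difference error bars
    (half-width MSD/2, so non-overlapping bars differ significantly)."""
    fig, ax = _axes((5, 4))
    labels = [g.label for g in groups]
    means = [g.mean for g in groups]
    half = (report.tukey.msd or 0.0) / 2.0
    ax.errorbar(
        labels, means, yerr=half, fmt="o", capsize=5, color="tab:blue"
    )
    iso = set(report.isolated_groups())
    for lab, m in zip(labels, means):
        if lab in iso:
            ax.annotate("*", (lab, m), textcoords="offset points",
                        xytext=(8, -4), fontsize=14)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel(r"$\overline{|M|_{norm}}$")
    ax.set_title(
        f"Tukey comparison (alpha={report.alpha_tukey}), "
        f"F={report.anova.F:.1f}"
    )
    fig.savefig(Path(path), dpi=150, bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(fig)
    return Path(path)
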
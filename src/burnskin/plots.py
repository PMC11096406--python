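"""Box-plot and bar-chart figures for the report bundle.

matplotlib is an optional dependency (install the ``plot`` extra); it is
imported lazily so the analysis pipeline never requires it.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .univariate import FEATURES


def _plt():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover - exercised without extra
        raise ImportError("plotting requires matplotlib (install burnskin[plot])") from exc
    return plt


def feature_box_plots(features: pd.DataFrame, path: str | Path) -> Path:
    """One box plot per material parameter, grouped by loading rate."""
    plt = _plt()
    rates = sorted(features["rate_mm_per_s"].unique())
    fig, axes = plt.subplots(1, len(FEATURES), figsize=(3 * len(FEATURES), 3.2))
    for ax, feat in zip(axes, FEATURES):
        data = [features.loc[features["rate_mm_per_s"] == r, feat] for r in rates]
        ax.boxplot(data, tick_labels=[f"{r:g}" for r in rates])
        ax.set_title(feat)
        ax.set_xlabel("rate (mm/s)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def contribution_bar_chart(contributions: pd.Series, path: str | Path) -> Path:
    """Bar chart of per-feature contribution fractions of the classifier."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(range(len(contributions)), contributions.to_numpy())
    ax.set_xticks(range(len(contributions)))
    ax.set_xticklabels(contributions.index, rotation=30, ha="right")
    ax.set_ylabel("contribution fraction")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
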
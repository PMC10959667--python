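"""Optional figure emission for similarity tables."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .containers import SimilarityTable


def plot_similarity_heatmap(table: SimilarityTable, path: str | Path, title: str | None = None):
    """Render a query x reference score heatmap to PNG or SVG."""
    fig, ax = plt.subplots(
        figsize=(1.2 * table.scores.shape[1] + 2, 0.6 * table.scores.shape[0] + 2)
    )
    vmin, vmax = (-1.0, 1.0) if table.metric == "cosine" else (0.0, 1.0)
    im = ax.imshow(table.scores.values, cmap="viridis", vmin=vmin, vmax=vmax, aspect="auto")
    ax.set_xticks(range(table.scores.shape[1]), table.scores.columns, rotation=45, ha="right")
    ax.set_yticks(range(table.scores.shape[0]), table.scores.index)
    ax.set_title(title or table.metric)
    fig.colorbar(im, ax=ax, label=table.metric)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
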
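"""Optional matplotlib rendering for the heat-map-ready matrices.

Rendering is metadata-first: analysis results never depend on images, and
the banded colour scheme mirrors the exported band annotation (|v| <= clip
neutral, above up, below down).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def render_heatmap(matrix: pd.DataFrame, out_path, clip: float = 0.6) -> None:
    """Render a set/gene x lot matrix as a banded heat map PNG."""
    vals = matrix.to_numpy(dtype=float)
    vmax = max(clip * 2, float(np.nanmax(np.abs(vals))) or 1.0)
    fig, ax = plt.subplots(
        figsize=(1 + 0.6 * matrix.shape[1], 1 + 0.25 * matrix.shape[0])
    )
    im = ax.imshow(vals, cmap="RdYlGn_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), labels=matrix.columns, rotation=45)
    ax.set_yticks(range(matrix.shape[0]), labels=matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
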
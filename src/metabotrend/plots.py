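"""Static per-stage figures: the scriptable analogue of interactive previews.

All functions write a file and return its path; they use the Agg backend so
they run headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clustering import ClusterModel
from .core_data import Dataset


def correction_before_after(
    before: Dataset, after: Dataset, peak_id: str, path: str | Path
) -> Path:
    """Intensity vs acquisition order for one peak, pre and post correction,
    colored by batch with QCs marked."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=False)
    for ax, ds, title in ((axes[0], before, "before"), (axes[1], after, "after")):
        acq = ds.obs["acq_order"]
        y = ds.values[peak_id]
        for b in dict.fromkeys(ds.obs["batch"]):
            m = (ds.obs["batch"] == b) & ~ds.is_qc
            ax.scatter(acq[m], y[m], s=12, label=f"batch {b}")
        qc = ds.is_qc
        if qc.any():
            ax.scatter(acq[qc], y[qc], s=18, c="k", marker="x", label="QC")
        ax.set_title(f"{peak_id} ({title})")
        ax.set_xlabel("acquisition order")
    axes[0].set_ylabel("intensity")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def cluster_small_multiples(model: ClusterModel, path: str | Path, max_cols: int = 5) -> Path:
    """Thumbnail grid of clusters: member vectors in grey, center in color."""
    k = model.k
    ncols = min(max_cols, k)
    nrows = int(np.ceil(k / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(2.2 * ncols, 1.8 * nrows), squeeze=False
    )
    x = np.arange(model.vectors.length)
    for c in range(k):
        ax = axes[c // ncols][c % ncols]
        members = model.assignment == c
        for row in model.vectors.matrix[members]:
            ax.plot(x, row, color="0.75", lw=0.5)
        ax.plot(x, model.centers[c], color="C0", lw=1.5)
        ax.set_title(f"cluster {c} (n={int(members.sum())})", fontsize=7)
        ax.tick_params(labelsize=6)
    for j in range(k, nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
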
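"""Plot helpers (confusion-matrix heatmaps)."""

from __future__ import annotations

import numpy as np


def plot_confusion_matrix(cm, ax=None, title: str = "", cmap: str = "Blues"):
    """Render a 5x5 true-vs-predicted severity count matrix."""
    import matplotlib.pyplot as plt

    cm = np.asarray(cm)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(cm, cmap=cmap)
    ax.set_xticks(range(cm.shape[1]))
    ax.set_yticks(range(cm.shape[0]))
    ax.set_xlabel("predicted score")
    ax.set_ylabel("true score")
    if title:
        ax.set_title(title)
    thresh = cm.max() / 2.0 if cm.max() > 0 else 0.5
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(
                j, i, str(int(cm[i, j])), ha="center", va="center",
                color="white" if cm[i, j] > thresh else "black", fontsize=9,
            )
    ax.figure.colorbar(im, ax=ax, fraction=0.046)
    return ax
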
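"""Prediction-distribution plots."""

from __future__ import annotations

import numpy as np

from .types import MetricsReport


def plot_score_histogram(report: MetricsReport, out_path: str) -> None:
    """Side-by-side per-class histogram of breast malignancy scores.

    Bar heights sum to 1 within each class, so shapes are comparable
    across classes regardless of imbalance.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = report.score_histogram
    n_bins = len(hist["benign"])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    width = (edges[1] - edges[0]) * 0.42

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(centers - width / 2, hist["benign"], width=width, label="benign", color="tab:blue")
    ax.bar(centers + width / 2, hist["malignant"], width=width, label="malignant", color="tab:red")
    ax.set_xlabel("malignancy score")
    ax.set_ylabel("fraction of breasts")
    ax.set_title(f"breast-wise scores (AUC = {report.auc:.3f})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
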
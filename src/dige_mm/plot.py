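"""Basic visualization helpers (volcano and spot heatmap)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .models import SpotModelResults, visualize_adjust
from .tmm import NormalizationResult


def volcano(results: SpotModelResults, coefficient: str, alpha: float = 0.05, ax=None):
    """log2 fold-change vs -log10 p for one coefficient."""
    sub = results.coefficient_frame(coefficient)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sig = sub["p"] < alpha
    ax.scatter(sub["estimate"][~sig], -np.log10(sub["p"][~sig]), s=6, c="grey", alpha=0.6)
    ax.scatter(sub["estimate"][sig], -np.log10(sub["p"][sig]), s=8, c="crimson", alpha=0.8)
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold-change")
    ax.set_ylabel("-log10 p")
    ax.set_title(coefficient)
    return ax


def spot_heatmap(
    normalized: NormalizationResult,
    results: SpotModelResults,
    spot_ids: list[str],
    ax=None,
):
    """Intercept-adjusted sample-channel heatmap for selected spots."""
    adjusted = visualize_adjust(normalized, results)["sample"]
    pos = {s: i for i, s in enumerate(normalized.spot_ids)}
    rows = np.array([pos[s] for s in spot_ids])
    block = adjusted[rows]
    block = block - block.mean(axis=1, keepdims=True)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.2 * len(spot_ids) + 1))
    im = ax.imshow(block, aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(spot_ids)), spot_ids, fontsize=6)
    ax.set_xticks(range(len(normalized.gel_ids)), normalized.gel_ids, rotation=90, fontsize=6)
    plt.colorbar(im, ax=ax, label="centered log2")
    return ax
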
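"""Advisory figures: MSE profiles, phase-colored PCA, concordance scatter.

Figures are diagnostics, not analysis outputs; nothing downstream reads
them.  All functions accept and return matplotlib axes so they compose, and
none mutates its inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "plot_mse_profile",
    "plot_pca_by_phase",
    "plot_concordance",
    "plot_hormone_overlay",
    "pca_embedding",
    "make_reports",
]

PHASE_COLORS = {"menstrual": "#c44e52", "proliferative": "#55a868", "secretory": "#4c72b0"}


def pca_embedding(em: pd.DataFrame) -> np.ndarray:
    """2-D PCA embedding of samples (gene-centered, deterministic signs)."""
    X = em.to_numpy(dtype=float).T
    X = X - X.mean(axis=0)
    pca = PCA(n_components=2, svd_solver="full")
    emb = pca.fit_transform(X)
    for j in range(2):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            emb[:, j] *= -1.0
    return emb


def plot_mse_profile(profile: pd.Series, sample_id: str = "", ax=None):
    ax = ax or plt.subplots()[1]
    ax.plot(profile.index.to_numpy(), profile.to_numpy(), lw=1.5)
    i = int(np.argmin(profile.to_numpy()))
    ax.axvline(profile.index[i], ls="--", color="grey", lw=1)
    ax.set_xlabel("model time")
    ax.set_ylabel("MSE")
    ax.set_title(f"MSE profile {sample_id}".strip())
    return ax


def plot_pca_by_phase(em: pd.DataFrame, phases: pd.Series, ax=None):
    ax = ax or plt.subplots()[1]
    emb = pca_embedding(em)
    phases = phases.reindex(em.columns)
    for phase, color in PHASE_COLORS.items():
        m = (phases == phase).to_numpy()
        ax.scatter(emb[m, 0], emb[m, 1], s=12, color=color, label=phase)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_concordance(est: pd.Series, ref: pd.Series, ax=None):
    ax = ax or plt.subplots()[1]
    ref = ref.reindex(est.index)
    ax.scatter(ref.to_numpy(), est.to_numpy(), s=10, alpha=0.7)
    ax.plot([0, 100], [0, 100], color="grey", lw=1, ls="--")
    ax.set_xlabel("reference cycle %")
    ax.set_ylabel("estimate cycle %")
    return ax


def plot_hormone_overlay(percentages: pd.Series, hormones: pd.DataFrame, ax=None):
    """Hormone levels against cycle percentage; skipped when empty."""
    if hormones is None or hormones.empty:
        logger.info("empty hormone table; overlay skipped")
        return None
    ax = ax or plt.subplots()[1]
    common = percentages.index.intersection(hormones.index)
    for col in hormones.columns:
        ax.scatter(percentages[common], hormones.loc[common, col], s=10, label=col, alpha=0.7)
    ax.set_xlabel("cycle %")
    ax.set_ylabel("hormone level")
    ax.legend(frameon=False, fontsize=8)
    return ax


def adjacent_pair_distance_ratio(em: pd.DataFrame, percentages: pd.Series) -> float:
    """Mean PC-space distance of cycle-adjacent sample pairs over the mean
    distance of random pairs; << 1 when the embedding is circularly ordered."""
    emb = pca_embedding(em)
    order = np.argsort(percentages.reindex(em.columns).to_numpy())
    ring = np.r_[order, order[0]]
    adj = np.mean(np.linalg.norm(emb[ring[1:]] - emb[ring[:-1]], axis=1))
    rng = np.random.default_rng(0)
    i = rng.integers(0, len(order), 2000)
    j = rng.integers(0, len(order), 2000)
    keep = i != j
    rand = np.mean(np.linalg.norm(emb[i[keep]] - emb[j[keep]], axis=1))
    return float(adj / rand)


def make_reports(result, out_dir, em: pd.DataFrame | None = None,
                 hormones: pd.DataFrame | None = None) -> list[str]:
    """Write the standard figure set for a pipeline result bundle.

    ``em`` is the input expression matrix (used for the PCA panel, where the
    cycle structure lives before normalization removes it); the normalized
    matrix stands in when it is not supplied.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    matrix = em if em is not None else result.normalized

    fig, ax = plt.subplots(figsize=(5, 4))
    plot_pca_by_phase(matrix, result.assignments["phase"], ax=ax)
    fig.savefig(out_dir / "pca_by_phase.png", dpi=120)
    plt.close(fig)
    written.append("pca_by_phase.png")

    sample = result.assignments.index[0]
    from .staging import estimate_sample_time

    prof = estimate_sample_time(matrix[sample], result.percentage_model)["mse_profile"]
    fig, ax = plt.subplots(figsize=(5, 3))
    plot_mse_profile(prof, sample_id=str(sample), ax=ax)
    fig.savefig(out_dir / "mse_profile_example.png", dpi=120)
    plt.close(fig)
    written.append("mse_profile_example.png")

    if hormones is not None and not hormones.empty:
        fig, ax = plt.subplots(figsize=(5, 3))
        plot_hormone_overlay(result.assignments["percentage"], hormones, ax=ax)
        fig.savefig(out_dir / "hormone_overlay.png", dpi=120)
        plt.close(fig)
        written.append("hormone_overlay.png")
    return written
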
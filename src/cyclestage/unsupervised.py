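"""Pathology-free staging: PCA, k-means, cluster ordering, cyclic fit.

A validation route that never sees stage labels: samples are embedded with
PCA (first two components of the gene-centered matrix), clustered by
k-means, and the clusters ordered along the cycle by the shortest open
Hamiltonian path through their centroids (the cyclic spline fit closes the
loop).  The ordered cluster index then serves as a proxy time axis: per-gene
penalized cyclic splines are fit against it, every sample is assigned a
continuous time by the same global-MSE loss as the supervised model, and
times are uniformized to 0–100.

Because an unsupervised cycle has no intrinsic origin or direction, the
comparison against a supervised staging aligns the two scales first: the
offset anchors the estimate at the reference's earliest menstrual sample and
both orientations are tried.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .metrics import circular_pearson, mean_abs_circular_difference
from .staging import MolecularStager, uniformize_times

__all__ = [
    "UnsupervisedStager",
    "ConcordanceReport",
    "unsupervised_stage",
    "order_clusters",
    "align_and_compare",
]


def order_clusters(centroids: np.ndarray) -> list[int]:
    """Order clusters along the cycle: minimal-length open Hamiltonian path
    through the centroids (exhaustive — intended for a handful of clusters).

    Of the two traversal directions the one starting at the lower cluster
    index is returned; orientation is resolved later by the alignment step.
    """
    k = len(centroids)
    if k > 8:
        raise ValueError("exhaustive ordering is intended for <= 8 clusters")
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    best, best_len = None, np.inf
    for perm in itertools.permutations(range(k)):
        if perm[0] > perm[-1]:  # canonical direction
            continue
        length = sum(d[perm[i], perm[i + 1]] for i in range(k - 1))
        if length < best_len - 1e-12:
            best, best_len = perm, length
    return list(best)


class UnsupervisedStager(BaseEstimator):
    """Label-free cyclic staging with fit/predict semantics.

    Parameters
    ----------
    n_clusters : number of k-means clusters on the 2-D PCA embedding.
    k_spline : cyclic spline basis dimension over the cluster-index axis.
    random_state : seed for k-means (PCA is deterministic by SVD with a
        fixed sign convention).
    grid_step : assignment grid step on the cluster-index axis.
    """

    def __init__(self, n_clusters=5, k_spline=6, random_state=0, grid_step=0.005):
        self.n_clusters = n_clusters
        self.k_spline = k_spline
        self.random_state = random_state
        self.grid_step = grid_step

    def fit(self, X, y=None):
        """X: samples x genes."""
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        if X.shape[0] < self.n_clusters:
            raise ValueError("fewer samples than clusters")
        centered = X.to_numpy(dtype=float) - X.to_numpy(dtype=float).mean(axis=0)
        pca = PCA(n_components=2, svd_solver="full")
        emb = pca.fit_transform(centered)
        # deterministic sign: largest-magnitude loading positive
        for j in range(emb.shape[1]):
            load = pca.components_[j]
            if load[np.argmax(np.abs(load))] < 0:
                emb[:, j] *= -1.0
        labels = None
        for attempt in range(5):
            km = KMeans(
                n_clusters=self.n_clusters,
                n_init=10,
                random_state=self.random_state + attempt,
            ).fit(emb)
            counts = np.bincount(km.labels_, minlength=self.n_clusters)
            if counts.min() > 0:
                labels = km.labels_
                break
            warnings.warn("empty k-means cluster; retrying with a new seed")
        if labels is None:
            raise ValueError("k-means produced an empty cluster in 5 attempts")
        tour = order_clusters(km.cluster_centers_)
        position = {c: i for i, c in enumerate(tour)}
        proxy = np.array([position[c] for c in labels], dtype=float)
        stager = MolecularStager(
            k=self.k_spline,
            cyclic=True,
            domain=(0.0, float(self.n_clusters)),
            grid_step=self.grid_step,
        )
        stager.fit(X, proxy)
        self.embedding_ = emb
        self.cluster_labels_ = labels
        self.cluster_ordering_ = tour
        self.centroids_ = km.cluster_centers_
        self.proxy_time_ = proxy
        self.stager_ = stager
        return self

    def predict(self, X):
        """Continuous model time on the cluster-index axis."""
        return self.stager_.predict(X)

    def fit_predict(self, X, y=None):
        return self.fit(X).predict(X)


def unsupervised_stage(
    em: pd.DataFrame, k_clusters: int = 5, k_spline: int = 6, seed: int = 0
) -> pd.DataFrame:
    """Stage a genes x samples matrix without labels.

    Returns an assignment table with model times on the cluster axis and
    uniformized percentages (origin and direction arbitrary).
    """
    stager = UnsupervisedStager(
        n_clusters=k_clusters, k_spline=k_spline, random_state=seed
    ).fit(em.T)
    assignments = stager.stager_.assign(em)
    assignments["cluster"] = stager.cluster_labels_
    assignments = uniformize_times(assignments, period=float(k_clusters))
    return assignments


@dataclass
class ConcordanceReport:
    """Agreement between two cyclic stagings after alignment."""

    circular_pearson_r: float
    mean_abs_circular_diff: float
    offset_used: float
    orientation: str  # "forward" | "reversed"
    aligned: pd.Series | None = None

    def to_dict(self) -> dict:
        return {
            "circular_pearson_r": self.circular_pearson_r,
            "mean_abs_circular_diff": self.mean_abs_circular_diff,
            "offset_used": self.offset_used,
            "orientation": self.orientation,
        }


def align_and_compare(
    est: pd.Series,
    ref: pd.Series,
    ref_ann: pd.DataFrame | None = None,
    period: float = 100.0,
) -> ConcordanceReport:
    """Align an unsupervised staging to a reference and report concordance.

    The candidate offsets anchor the estimate's value for the reference's
    earliest menstrual sample to that sample's reference value; both
    orientations are tried (the cyclic direction is unidentifiable) and the
    pair maximizing the circular Pearson correlation is reported.  Without a
    menstrual sample in ``ref_ann`` the offset is chosen on a 0.5-point grid.
    """
    est = est.reindex(ref.index)
    if est.isna().any():
        raise ValueError("estimate and reference must cover the same samples")
    ref_v = ref.to_numpy(dtype=float)
    candidates = []
    anchor = None
    if ref_ann is not None and "stage" in ref_ann.columns:
        menstrual = ref_ann.index[(ref_ann["stage"] == 1) & ref_ann.index.isin(ref.index)]
        if len(menstrual):
            anchor = ref[menstrual].idxmin()
    for orientation in ("forward", "reversed"):
        vals = est.to_numpy(dtype=float)
        if orientation == "reversed":
            vals = np.mod(period - vals, period)
        if anchor is not None:
            offsets = [float(np.mod(ref[anchor] - vals[ref.index.get_loc(anchor)], period))]
        else:
            offsets = list(np.arange(0.0, period, 0.5))
        for off in offsets:
            aligned = np.mod(vals + off, period)
            r = circular_pearson(aligned, ref_v, period)
            candidates.append((r, orientation, off, aligned))
    r, orientation, off, aligned = max(candidates, key=lambda c: c[0])
    return ConcordanceReport(
        circular_pearson_r=float(r),
        mean_abs_circular_diff=mean_abs_circular_difference(aligned, ref_v, period),
        offset_used=float(off),
        orientation=orientation,
        aligned=pd.Series(aligned, index=ref.index, name="aligned_percentage"),
    )
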
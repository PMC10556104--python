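"""The molecular staging model: continuous cycle-time assignment.

For each gene g a penalized regression spline f_g(t) describes expected
log2 expression as a function of a coarse training time axis (pathologist
post-ovulatory day, a 3-stage secretory axis, or the 7 stages of the whole
cycle on a circle).  A sample with observed expression y_g is then placed at
the time d minimizing the global loss

    L(d) = sum_g (y_g - f_g(d))^2

evaluated on a dense grid, i.e. the time whose expected transcriptome is
closest to the observed one in mean squared error across all genes
simultaneously.  Because the cohort is assumed uniformly spread around the
cycle, assigned times are then *uniformized*: samples are ranked in cyclic
order and placed equidistantly on a 0–100 scale, read as the percentage of
the way through the cycle.  Gene curves are refit on the percentage axis
with a richer cyclic basis, which supports (a) normalizing expression for
cycle stage (residual + gene mean) and (b) staging of entirely new cohorts,
including cross-platform ones after per-gene median centering.

`MolecularStager` is the scikit-learn-shaped core (fit on samples x genes
with training times, predict times for new samples); the module-level
functions implement the named workflow steps on top of it.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator

from .io import pod_estimates
from .splines import CurveSet, SplineSpec, fit_curve_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "MolecularStager",
    "StagingModel",
    "estimate_sample_time",
    "stage_secretory",
    "reassign_proliferative",
    "fit_whole_cycle",
    "uniformize_times",
    "refit_percentage",
    "normalize_for_cycle",
    "phase_of",
    "crossvalidate_staging",
    "apply_model",
    "DEFAULT_PHASE_BOUNDARIES",
]

#: menstrual / proliferative / secretory cut points on the percentage scale
DEFAULT_PHASE_BOUNDARIES = (8.0, 58.0)

#: default assignment grid steps per time-axis kind
DEFAULT_GRID_STEP = {
    "pod_14day": 0.01,
    "stage_3sec": 0.005,
    "stage_7cyclic": 0.005,
    "percentage_cyclic": 0.05,
    "cluster_cyclic": 0.005,
}

MIN_GENE_OVERLAP = 0.5


# ---------------------------------------------------------------------------
# Core estimator


class MolecularStager(BaseEstimator):
    """Spline-curve staging model with fit/predict semantics.

    Parameters
    ----------
    k : int
        Spline basis dimension for the per-gene curves.
    cyclic : bool
        Periodic time axis.
    domain : tuple
        ``(t_min, t_max)``; for cyclic axes the period is the domain length.
    grid_step : float
        Step of the dense grid on which the MSE loss is minimized.
    lambdas : array-like or None
        Smoothing-parameter grid for GCV (default: the shared log grid).
    standardize : bool
        If True, each gene's squared residual in the loss is divided by the
        curve's residual variance.  Off by default: the loss is on raw log2
        residuals.

    Attributes (after fit)
    ----------------------
    curves_ : CurveSet of per-gene penalized splines.
    gene_ids_ : list of gene identifiers (model order).
    gene_means_ : per-gene training means (pandas Series).
    grid_ : the assignment time grid.
    """

    def __init__(self, k=8, cyclic=True, domain=(1.0, 8.0), grid_step=0.005,
                 lambdas=None, standardize=False):
        self.k = k
        self.cyclic = cyclic
        self.domain = domain
        self.grid_step = grid_step
        self.lambdas = lambdas
        self.standardize = standardize

    # X: samples x genes (DataFrame preferred), y: per-sample training times
    def fit(self, X, y):
        X = self._as_frame(X)
        t = np.asarray(y, dtype=float)
        if len(t) != X.shape[0]:
            raise ValueError("one training time per sample required")
        spec = SplineSpec(k=self.k, cyclic=self.cyclic, domain=tuple(map(float, self.domain)))
        self.curves_ = fit_curve_matrix(
            t, X.to_numpy(dtype=float), spec, list(X.columns), lambdas=self.lambdas
        )
        self.gene_ids_ = list(X.columns)
        self.gene_means_ = X.mean(axis=0)
        lo, hi = spec.domain
        n_steps = int(np.floor((hi - lo) / self.grid_step + 1e-9))
        # cyclic grids exclude the duplicated seam point at t_max
        self.grid_ = lo + self.grid_step * np.arange(n_steps + (0 if self.cyclic else 1))
        if not self.cyclic and self.grid_[-1] < hi - 1e-12:
            self.grid_ = np.append(self.grid_, hi)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"g{i}" for i in range(X.shape[1])])

    def _align(self, X: pd.DataFrame) -> tuple[pd.DataFrame, CurveSet]:
        """Subset to the gene intersection, enforcing minimum coverage."""
        present = [g for g in self.gene_ids_ if g in X.columns]
        frac = len(present) / len(self.gene_ids_)
        if frac < MIN_GENE_OVERLAP:
            raise ValueError(
                f"gene overlap with the model is {frac:.1%}, below the "
                f"{MIN_GENE_OVERLAP:.0%} minimum"
            )
        if frac < 1.0:
            logger.warning(
                "%d of %d model genes missing from the input; they are "
                "dropped from the loss", len(self.gene_ids_) - len(present),
                len(self.gene_ids_),
            )
            return X[present], self.curves_.subset(present)
        return X[self.gene_ids_], self.curves_

    def mse_profiles(self, X) -> pd.DataFrame:
        """MSE(d) on the grid for every sample: (n_grid x n_samples)."""
        X = self._as_frame(X)
        Xa, curves = self._align(X)
        F = curves.predict(self.grid_)  # (T, G)
        Y = Xa.to_numpy(dtype=float).T  # (G, S)
        if self.standardize:
            w = 1.0 / np.maximum(curves.residual_sd, 1e-6) ** 2
            Fw = F * np.sqrt(w)[None, :]
            Yw = Y * np.sqrt(w)[:, None]
            mse = (
                (Fw**2).sum(axis=1)[:, None] - 2.0 * Fw @ Yw + (Yw**2).sum(axis=0)[None, :]
            ) / w.sum()
        else:
            G = F.shape[1]
            mse = (
                (F**2).sum(axis=1)[:, None] - 2.0 * F @ Y + (Y**2).sum(axis=0)[None, :]
            ) / G
        index = pd.Index(self.grid_, name="time")
        cols = Xa.index if isinstance(Xa.index, pd.Index) else None
        return pd.DataFrame(mse, index=index, columns=cols)

    def predict(self, X):
        """Model time per sample: grid argmin of the MSE loss (ties break to
        the smallest grid time)."""
        prof = self.mse_profiles(X)
        vals = prof.to_numpy()
        idx = np.argmin(vals, axis=0)  # first minimum = smallest time
        flat = np.isclose(vals.max(axis=0), vals.min(axis=0))
        if flat.any():
            warnings.warn(
                "flat MSE profile for some samples (all curves constant?); "
                "tie broken to the smallest grid time"
            )
        return self.grid_[idx]

    def assign(self, em: pd.DataFrame) -> pd.DataFrame:
        """Assignment table for a genes x samples matrix."""
        prof = self.mse_profiles(em.T)
        vals = prof.to_numpy()
        idx = np.argmin(vals, axis=0)
        return pd.DataFrame(
            {
                "model_time": self.grid_[idx],
                "min_mse": vals[idx, np.arange(vals.shape[1])],
            },
            index=pd.Index(em.columns, name="sample_id"),
        )


# ---------------------------------------------------------------------------
# Serializable model bundle


@dataclass
class StagingModel:
    """A fitted staging model: curves, axis, grid and normalization state."""

    curves: CurveSet
    time_axis_kind: str
    grid_step: float
    gene_means: pd.Series
    phase_boundaries: tuple[float, float] = DEFAULT_PHASE_BOUNDARIES
    training_assignments: pd.DataFrame | None = None

    def _stager(self, standardize: bool = False) -> MolecularStager:
        spec = self.curves.spec
        st = MolecularStager(
            k=spec.k, cyclic=spec.cyclic, domain=spec.domain,
            grid_step=self.grid_step, standardize=standardize,
        )
        st.curves_ = self.curves
        st.gene_ids_ = list(self.curves.gene_ids)
        st.gene_means_ = self.gene_means
        lo, hi = spec.domain
        n_steps = int(np.floor((hi - lo) / self.grid_step + 1e-9))
        st.grid_ = lo + self.grid_step * np.arange(n_steps + (0 if spec.cyclic else 1))
        if not spec.cyclic and st.grid_[-1] < hi - 1e-12:
            st.grid_ = np.append(st.grid_, hi)
        st.n_features_in_ = len(st.gene_ids_)
        return st

    def assign(self, em: pd.DataFrame, standardize: bool = False) -> pd.DataFrame:
        return self._stager(standardize).assign(em)

    def to_dict(self) -> dict:
        d = {
            "time_axis_kind": self.time_axis_kind,
            "grid_step": self.grid_step,
            "phase_boundaries": list(self.phase_boundaries),
            "gene_means": self.gene_means.to_dict(),
            "curves": self.curves.to_dict(),
        }
        if self.training_assignments is not None:
            d["training_assignments"] = self.training_assignments.reset_index().to_dict(
                orient="list"
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StagingModel":
        curves = CurveSet.from_dict(d["curves"])
        means = pd.Series(d["gene_means"]).reindex(curves.gene_ids)
        train = None
        if "training_assignments" in d:
            train = pd.DataFrame(d["training_assignments"]).set_index("sample_id")
        return cls(
            curves=curves,
            time_axis_kind=d["time_axis_kind"],
            grid_step=float(d["grid_step"]),
            gene_means=means,
            phase_boundaries=tuple(d["phase_boundaries"]),
            training_assignments=train,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "StagingModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def estimate_sample_time(y: pd.Series, model: StagingModel) -> dict:
    """Stage a single sample.

    ``y`` is expression indexed by gene id.  Returns the model time (grid
    argmin of the MSE loss), the minimum MSE and the full profile for
    plotting.
    """
    if model.curves.n_genes == 0:
        raise ValueError("empty staging model")
    em = y.to_frame(name=y.name or "sample")
    st = model._stager()
    prof = st.mse_profiles(em.T)
    vals = prof.to_numpy()[:, 0]
    i = int(np.argmin(vals))
    return {
        "sample_id": em.columns[0],
        "model_time": float(st.grid_[i]),
        "min_mse": float(vals[i]),
        "mse_profile": pd.Series(vals, index=prof.index, name="mse"),
    }


# ---------------------------------------------------------------------------
# Workflow steps


def _pod_training(ann: pd.DataFrame, tolerance_days: float = 2.0) -> pd.Series:
    """Mean pathologist POD for samples whose calls agree within tolerance."""
    pods = pod_estimates(ann)
    if pods.empty:
        return pd.Series(dtype=float)
    n_calls = pods.notna().sum(axis=1)
    spread = pods.max(axis=1) - pods.min(axis=1)
    ok = (n_calls >= 2) & (spread <= tolerance_days)
    return pods[ok].mean(axis=1)


def stage_secretory(
    em: pd.DataFrame,
    ann: pd.DataFrame,
    mode: str = "pod_14day",
    grid_step: float | None = None,
    lambdas: ArrayLike | None = None,
    min_training: int = 10,
) -> tuple[StagingModel, pd.DataFrame]:
    """Secretory-phase staging model.

    ``mode='pod_14day'``: train on samples whose pathologist POD calls agree
    within 2 days (training time = their mean), non-cyclic k=3 splines on
    [1, 14].  ``mode='stage_3sec'``: train on stage labels 5/6/7 used as
    numeric times, domain [4.5, 7.5].  Every sample of ``em`` is then
    assigned a continuous time on the training domain.
    """
    if mode == "pod_14day":
        t_train = _pod_training(ann)
        domain = (1.0, 14.0)
    elif mode == "stage_3sec":
        stages = ann["stage"].dropna()
        stages = stages[stages.isin([5, 6, 7])]
        t_train = stages.astype(float)
        domain = (4.5, 7.5)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    t_train = t_train[t_train.index.isin(em.columns)]
    if len(t_train) < min_training:
        raise ValueError(
            f"only {len(t_train)} eligible training samples (need >= {min_training})"
        )
    step = DEFAULT_GRID_STEP[mode] if grid_step is None else grid_step
    stager = MolecularStager(
        k=3, cyclic=False, domain=domain, grid_step=step, lambdas=lambdas
    )
    Xtr = em[t_train.index].T
    stager.fit(Xtr, t_train.to_numpy())
    model = StagingModel(
        curves=stager.curves_,
        time_axis_kind=mode,
        grid_step=step,
        gene_means=stager.gene_means_,
    )
    assignments = model.assign(em)
    assignments["training_time"] = t_train.reindex(assignments.index)
    model.training_assignments = assignments
    return model, assignments


def reassign_proliferative(
    em: pd.DataFrame, ann: pd.DataFrame, lambdas: ArrayLike | None = None
) -> pd.DataFrame:
    """Split proliferative samples into early/mid/late by molecular time.

    A non-cyclic k=3 spline is fit per gene on the axis menstrual -> 0,
    proliferative -> 1, early secretory -> 2; proliferative samples get a
    continuous time by MSE minimization and are split, in time order, into
    three contiguous groups as equal as possible (earlier groups take the
    remainder), relabelled stages 2/3/4.  Returns a copy of the annotation
    with the new stages and the continuous times in ``reassign_time``.
    """
    stage = ann["stage"]
    menstrual = stage[stage == 1].index
    prolif = stage[stage.isin([2, 3, 4])].index
    early_sec = stage[stage == 5].index
    if len(prolif) < 3:
        raise ValueError("need at least 3 proliferative samples to reassign")
    if len(menstrual) == 0 or len(early_sec) == 0:
        raise ValueError("reassignment needs menstrual and early-secretory samples")
    axis = pd.concat(
        [
            pd.Series(0.0, index=menstrual),
            pd.Series(1.0, index=prolif),
            pd.Series(2.0, index=early_sec),
        ]
    )
    axis = axis[axis.index.isin(em.columns)]
    stager = MolecularStager(
        k=3, cyclic=False, domain=(0.0, 2.0), grid_step=0.005, lambdas=lambdas
    )
    stager.fit(em[axis.index].T, axis.to_numpy())
    times = pd.Series(stager.predict(em[prolif].T), index=prolif)
    if np.ptp(times.to_numpy()) == 0:
        raise ValueError(
            "all proliferative samples received the same time; the curves "
            "carry no signal over this axis — consider more genes"
        )
    # deterministic order: estimated time, then sample id
    ordered = sorted(prolif, key=lambda s: (times[s], str(s)))
    n = len(ordered)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    new_ann = ann.copy()
    new_ann["reassign_time"] = np.nan
    new_ann.loc[prolif, "reassign_time"] = times
    start = 0
    for label, size in zip((2, 3, 4), sizes):
        members = ordered[start : start + size]
        new_ann.loc[members, "stage"] = label
        start += size
    return new_ann


def fit_whole_cycle(
    em: pd.DataFrame,
    ann: pd.DataFrame,
    grid_step: float | None = None,
    lambdas: ArrayLike | None = None,
) -> tuple[StagingModel, pd.DataFrame]:
    """Whole-cycle staging from 7 stage labels.

    Stages 1..7 are encoded as times 1..7 on a cyclic axis of period 7
    (domain [1, 8), seam between stage 7 and stage 1); per-gene cyclic k=8
    splines are fit and every sample assigned a continuous model time.
    """
    stage = ann["stage"].dropna().astype(int)
    stage = stage[stage.index.isin(em.columns)]
    present = sorted(stage.unique())
    if len(present) < 3:
        raise ValueError(f"need >= 3 distinct stages, got {present}")
    missing = sorted(set(range(1, 8)) - set(present))
    if missing:
        warnings.warn(f"stages entirely absent from training data: {missing}")
    step = DEFAULT_GRID_STEP["stage_7cyclic"] if grid_step is None else grid_step
    stager = MolecularStager(
        k=8, cyclic=True, domain=(1.0, 8.0), grid_step=step, lambdas=lambdas
    )
    stager.fit(em[stage.index].T, stage.to_numpy(dtype=float))
    model = StagingModel(
        curves=stager.curves_,
        time_axis_kind="stage_7cyclic",
        grid_step=step,
        gene_means=stager.gene_means_,
    )
    assignments = model.assign(em)
    model.training_assignments = assignments
    return model, assignments


def uniformize_times(
    assignments: pd.DataFrame,
    period: float | None = None,
    anchor_times: ArrayLike | None = None,
    time_column: str = "model_time",
) -> pd.DataFrame:
    """Spread samples equidistantly on 0–100 in cyclic time order.

    Samples are ranked by model time (ties broken by sample id) and given
    ``percentage = 100 * (rank - 0.5) / n``.  On a cyclic axis the ranking
    starts at an origin: by default the smallest time, or — when
    ``anchor_times`` holds the model times of the menstrual (stage-1)
    training samples — the earliest sample within that circular cluster, so
    0% lines up with menstruation onset.
    """
    if len(assignments) < 2:
        raise ValueError("uniformization needs at least 2 samples")
    out = assignments.copy()
    times = out[time_column].to_numpy(dtype=float)
    if period is not None and anchor_times is not None and len(np.atleast_1d(anchor_times)):
        anchor = np.atleast_1d(np.asarray(anchor_times, dtype=float))
        ang = 2 * np.pi * anchor / period
        mu = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) * period / (2 * np.pi)
        rel = np.mod(anchor - mu + period / 2, period) - period / 2
        origin = anchor[int(np.argmin(rel))]
    else:
        origin = times.min()
    key = np.mod(times - origin, period) if period is not None else times - origin
    order = sorted(range(len(out)), key=lambda i: (key[i], str(out.index[i])))
    ranks = np.empty(len(out))
    ranks[order] = np.arange(1, len(out) + 1)
    out["percentage"] = 100.0 * (ranks - 0.5) / len(out)
    return out


def refit_percentage(
    em: pd.DataFrame,
    percentages: pd.Series | ArrayLike,
    k: int = 30,
    lambdas: ArrayLike | None = None,
) -> CurveSet:
    """Refit per-gene curves on the 0–100 percentage axis (cyclic, period
    100) with a richer basis."""
    if isinstance(percentages, pd.Series):
        pct = percentages.reindex(em.columns).to_numpy(dtype=float)
    else:
        pct = np.asarray(percentages, dtype=float)
    if np.any(pct < 0) or np.any(pct >= 100):
        raise ValueError("percentages must lie in [0, 100)")
    spec = SplineSpec(k=k, cyclic=True, domain=(0.0, 100.0))
    return fit_curve_matrix(pct, em.to_numpy(dtype=float).T, spec, list(em.index), lambdas)


def normalize_for_cycle(
    em: pd.DataFrame, curve_set: CurveSet, percentages: pd.Series | ArrayLike
) -> pd.DataFrame:
    """Normalize expression for cycle stage: residual from the fitted curve
    plus the gene's mean (per-gene means are preserved exactly)."""
    if list(curve_set.gene_ids) != list(em.index):
        if set(curve_set.gene_ids) >= set(em.index):
            curve_set = curve_set.subset(list(em.index))
        else:
            missing = sorted(set(em.index) - set(curve_set.gene_ids))[:5]
            raise ValueError(f"curve set lacks genes present in the matrix: {missing}")
    if isinstance(percentages, pd.Series):
        pct = percentages.reindex(em.columns).to_numpy(dtype=float)
    else:
        pct = np.asarray(percentages, dtype=float)
    fitted = curve_set.predict(pct).T  # (G, S)
    vals = em.to_numpy(dtype=float)
    resid = vals - fitted
    out = resid + vals.mean(axis=1, keepdims=True) - resid.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=em.index, columns=em.columns)


def phase_of(
    percentage: ArrayLike, boundaries: tuple[float, float] = DEFAULT_PHASE_BOUNDARIES
):
    """Phase label(s) for percentages: menstrual [0, b1), proliferative
    [b1, b2), secretory [b2, 100)."""
    p = np.asarray(percentage, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if np.any(p < 0) or np.any(p >= 100):
        raise ValueError("percentage out of [0, 100)")
    b1, b2 = boundaries
    out = np.where(p < b1, "menstrual", np.where(p < b2, "proliferative", "secretory"))
    return out[0] if scalar else out


def crossvalidate_staging(
    em: pd.DataFrame,
    ann: pd.DataFrame,
    K: int = 5,
    seed: int = 0,
    mode: str = "pod_14day",
) -> dict:
    """K-fold cross-validation of the secretory staging model.

    Eligible training samples are partitioned into K seeded folds; curves
    are fit on K-1 folds and held-out samples assigned times.  Reports the
    pooled and per-fold Pearson correlation of held-out times with the
    pathology training times, next to the in-sample correlation.
    """
    if mode == "pod_14day":
        t_train = _pod_training(ann)
    else:
        stages = ann["stage"].dropna()
        t_train = stages[stages.isin([5, 6, 7])].astype(float)
    t_train = t_train[t_train.index.isin(em.columns)]
    n = len(t_train)
    if n < K:
        raise ValueError(f"{n} eligible samples cannot fill {K} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [sorted(perm[i::K]) for i in range(K)]
    if min(len(f) for f in folds) < 2:
        raise ValueError("a fold has fewer than 2 samples; reduce K")
    samples = t_train.index.to_numpy()
    held_est, held_true = [], []
    fold_rs = []
    fold_assign = {}
    for fold in folds:
        test_ids = samples[list(fold)]
        train_ids = [s for s in samples if s not in set(test_ids)]
        sub_ann = ann.loc[train_ids]
        model, _ = stage_secretory(em[train_ids], sub_ann, mode=mode)
        est = model.assign(em[test_ids])["model_time"]
        truth = t_train[test_ids]
        held_est.append(est.to_numpy())
        held_true.append(truth.to_numpy())
        fold_assign.update(est.to_dict())
        fold_rs.append(float(pearsonr(est.to_numpy(), truth.to_numpy()).statistic))
    pooled_est = np.concatenate(held_est)
    pooled_true = np.concatenate(held_true)
    model_full, assignments = stage_secretory(em, ann, mode=mode)
    in_sample = assignments.loc[t_train.index, "model_time"].to_numpy()
    return {
        "K": K,
        "seed": seed,
        "n_training": n,
        "folds": [samples[list(f)].tolist() for f in folds],
        "per_fold_r": fold_rs,
        "pooled_heldout_r": float(pearsonr(pooled_est, pooled_true).statistic),
        "in_sample_r": float(pearsonr(in_sample, t_train.to_numpy()).statistic),
        "heldout_times": fold_assign,
    }


def apply_model(
    model: StagingModel,
    em_new: pd.DataFrame,
    center: str | None = "median",
    re_uniformize: bool = False,
) -> pd.DataFrame:
    """Stage a new cohort with a fitted percentage-axis model.

    Both the model curves and the new samples are per-gene centered on the
    gene intersection before the MSE assignment (medians by default), which
    removes cross-platform location shifts.  Percentages are read directly
    off the model's percentage axis; ``re_uniformize`` optionally re-ranks
    the new cohort instead.
    """
    present = [g for g in model.curves.gene_ids if g in em_new.index]
    frac = len(present) / model.curves.n_genes
    if frac < MIN_GENE_OVERLAP:
        raise ValueError(
            f"gene coverage {frac:.1%} is below the {MIN_GENE_OVERLAP:.0%} minimum"
        )
    curves = model.curves.subset(present) if frac < 1.0 else model.curves
    spec = curves.spec
    lo, hi = spec.domain
    n_steps = int(np.floor((hi - lo) / model.grid_step + 1e-9))
    grid = lo + model.grid_step * np.arange(n_steps + (0 if spec.cyclic else 1))
    F = curves.predict(grid)  # (T, G)
    Y = em_new.loc[present].to_numpy(dtype=float)  # (G, S)
    if center == "median":
        F = F - np.median(F, axis=0)[None, :]
        Y = Y - np.median(Y, axis=1)[:, None]
    elif center == "mean":
        F = F - F.mean(axis=0)[None, :]
        Y = Y - Y.mean(axis=1)[:, None]
    elif center is not None:
        raise ValueError(f"unknown centering {center!r}")
    G = F.shape[1]
    mse = ((F**2).sum(axis=1)[:, None] - 2.0 * F @ Y + (Y**2).sum(axis=0)[None, :]) / G
    idx = np.argmin(mse, axis=0)
    out = pd.DataFrame(
        {
            "model_time": grid[idx],
            "min_mse": mse[idx, np.arange(mse.shape[1])],
        },
        index=pd.Index(em_new.columns, name="sample_id"),
    )
    if spec.cyclic and np.isclose(spec.period, 100.0):
        out["percentage"] = np.mod(out["model_time"].to_numpy(), 100.0)
    if re_uniformize:
        out = uniformize_times(out, period=spec.period if spec.cyclic else None)
    if "percentage" in out.columns:
        out["phase"] = phase_of(out["percentage"].to_numpy(), model.phase_boundaries)
    return out
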
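"""Cycle-aware differential expression statistics.

Gene-wise ordinary least squares against an arbitrary design (cycle-time
spline columns, age, group contrasts, batch dummies), with empirical-Bayes
variance moderation: the per-gene residual variances s_g^2 (d_g df) are
shrunk toward a prior s_0^2 with d_0 df estimated by moment matching of
log s_g^2 against a scaled F distribution (Smyth 2004).  The moderated
t-statistic uses the posterior variance

    s_post^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

on d_0 + d_g degrees of freedom.  A *treat*-style test against a minimum
fold change tests |beta| >= tau with the shifted-null construction

    p = P(T > (|beta| - tau)/se) + P(T > (|beta| + tau)/se).

On top of these sit the sliding-window scan (consecutive rank blocks of the
cycle ordering compared two-group with the treat test and per-window BH
correction), the weighted Fisher combination of per-study p-values (each
study's contribution a Gamma(w_i, 2) quantile, weights proportional to
sample size and summing to the number of studies), and the overlap of
scan hits with a reference gene list inside a cycle window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .splines import SplineBasis, SplineSpec
from .staging import DEFAULT_PHASE_BOUNDARIES, phase_of

__all__ = [
    "DesignMatrix",
    "GenewiseFit",
    "ModeratedResult",
    "WindowScanResult",
    "build_design",
    "cycle_spline_columns",
    "fit_genewise",
    "ebayes_moderate",
    "bh_adjust",
    "sliding_window_scan",
    "wfisher_meta",
    "rapid_gene_overlap",
]


# ---------------------------------------------------------------------------
# Designs


def cycle_spline_columns(
    percentages: ArrayLike,
    df: int = 8,
    cyclic: bool = True,
    domain: tuple[float, float] = (0.0, 100.0),
) -> pd.DataFrame:
    """Spline basis columns for a cycle-time covariate.

    Returns ``df`` centered columns spanning the smooth (the constant
    function is removed so the columns can sit next to an intercept).
    """
    p = np.asarray(percentages, dtype=float)
    # df + 1 free coefficients; centering kills the constant direction and
    # dropping any one column leaves df independent columns
    k = df + 2 if cyclic else df + 1
    spec = SplineSpec(k=k, cyclic=cyclic, domain=domain)
    basis = SplineBasis.from_times(p, spec)
    X = basis.design(p)
    X = X - X.mean(axis=0)
    X = X[:, :df]
    return pd.DataFrame(X, columns=[f"cycle{i + 1}" for i in range(X.shape[1])])


@dataclass
class DesignMatrix:
    """Design with a named target coefficient."""

    matrix: pd.DataFrame  # samples x columns, full column rank
    target: str

    def __post_init__(self):
        X = self.matrix.to_numpy(dtype=float)
        r = np.linalg.matrix_rank(X)
        if r < X.shape[1]:
            # name the collinear columns: those whose removal restores rank
            collinear = [
                c
                for i, c in enumerate(self.matrix.columns)
                if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == r
            ]
            raise ValueError(f"design is rank deficient; collinear columns: {collinear}")
        if self.target not in self.matrix.columns:
            raise ValueError(f"target column {self.target!r} not in the design")


def build_design(
    n: int,
    target: str,
    percentages: ArrayLike | None = None,
    cycle_df: int = 8,
    cyclic: bool = True,
    cycle_domain: tuple[float, float] = (0.0, 100.0),
    age: ArrayLike | None = None,
    group: ArrayLike | None = None,
    batch: ArrayLike | None = None,
    index=None,
) -> DesignMatrix:
    """Assemble intercept + cycle spline + covariates into a design."""
    cols = {"intercept": np.ones(n)}
    frame = pd.DataFrame(cols, index=index)
    if percentages is not None:
        sp = cycle_spline_columns(percentages, df=cycle_df, cyclic=cyclic, domain=cycle_domain)
        sp.index = frame.index
        frame = pd.concat([frame, sp], axis=1)
    if age is not None:
        frame["age"] = np.asarray(age, dtype=float)
    if group is not None:
        dummies = pd.get_dummies(pd.Series(np.asarray(group), index=frame.index), prefix="group", drop_first=True)
        frame = pd.concat([frame, dummies.astype(float)], axis=1)
    if batch is not None:
        dummies = pd.get_dummies(pd.Series(np.asarray(batch), index=frame.index), prefix="batch", drop_first=True)
        frame = pd.concat([frame, dummies.astype(float)], axis=1)
    return DesignMatrix(matrix=frame, target=target)


# ---------------------------------------------------------------------------
# Gene-wise OLS


@dataclass
class GenewiseFit:
    """Per-gene OLS results for one shared design."""

    coefficients: pd.DataFrame  # genes x design columns
    stdev_unscaled: pd.Series  # per design column: sqrt[(X'X)^-1_jj]
    sigma2: pd.Series  # per gene residual variance s_g^2
    df_residual: int
    design: DesignMatrix


def fit_genewise(em: pd.DataFrame, design: DesignMatrix) -> GenewiseFit:
    """Ordinary least squares of every gene on the design."""
    X = design.matrix.to_numpy(dtype=float)
    n, q = X.shape
    if em.shape[1] != n:
        raise ValueError("matrix and design disagree on the number of samples")
    if n <= q:
        raise ValueError(f"need more samples ({n}) than design columns ({q})")
    Y = em.to_numpy(dtype=float).T  # samples x genes
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ Y  # q x G
    resid = Y - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    df = n - q
    s2 = rss / df
    return GenewiseFit(
        coefficients=pd.DataFrame(coef.T, index=em.index, columns=design.matrix.columns),
        stdev_unscaled=pd.Series(np.sqrt(np.diag(XtX_inv)), index=design.matrix.columns),
        sigma2=pd.Series(s2, index=em.index, name="sigma2"),
        df_residual=df,
        design=design,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    return float(optimize.brentq(lambda x: special.polygamma(1, x) - y, 1e-8, 1e8, xtol=1e-12))


def estimate_variance_prior(s2: NDArray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the observed log residual variances.

    Under the hierarchical model, e_g = log s_g^2 - psi(d_g/2) + log(d_g/2)
    has mean log s0^2 - psi(d0/2) + log(d0/2) and excess variance
    psi'(d0/2) beyond psi'(d_g/2); inverting the trigamma gives d0.
    Identical variances (or none in excess) give d0 = infinity.
    """
    s2 = np.asarray(s2, dtype=float)
    if len(s2) < 2:
        raise ValueError("need at least 2 genes to estimate the prior")
    ok = s2 > 0
    if not ok.any():
        return np.inf, 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(np.mean(e))
    n = len(e)
    if n < 2:
        return np.inf, float(np.mean(s2[ok]))
    excess = float(np.mean((e - ebar) ** 2) * n / (n - 1) - special.polygamma(1, df / 2.0))
    if excess <= 0:
        # no spread beyond sampling noise: completely pooled variance
        return np.inf, float(np.mean(s2[ok]))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def posterior_variance(s2: NDArray, df: float, d0: float, s0_sq: float) -> NDArray:
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0_sq)
    return (d0 * s0_sq + df * np.asarray(s2, dtype=float)) / (d0 + df)


@dataclass
class ModeratedResult:
    """Moderated (optionally treat) test of one design coefficient."""

    table: pd.DataFrame  # gene_id, logFC, t, p, p_adj
    d0: float
    s0_sq: float
    lfc_threshold: float
    target: str

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["p_adj"] < 0.05]


def ebayes_moderate(
    fit: GenewiseFit,
    target: str | None = None,
    lfc_threshold: float = 0.0,
    d0_override: float | None = None,
) -> ModeratedResult:
    """Moderated t (or treat) test for the design's target coefficient.

    ``lfc_threshold`` is a fold change (e.g. 1.2); on the log2 scale of the
    coefficients the test is against tau = log2(threshold).  ``d0_override``
    forces the prior df (0 recovers the ordinary t-test exactly).
    """
    target = fit.design.target if target is None else target
    beta = fit.coefficients[target].to_numpy()
    su = float(fit.stdev_unscaled[target])
    s2 = fit.sigma2.to_numpy()
    df = fit.df_residual
    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = np.nan if d0 == 0 else estimate_variance_prior(s2, df)[1]
        s_post = s2.copy() if d0 == 0 else posterior_variance(s2, df, d0, s0_sq)
    else:
        d0, s0_sq = estimate_variance_prior(s2, df)
        s_post = posterior_variance(s2, df, d0, s0_sq)
    df_total = np.inf if np.isinf(d0) else df + d0
    se = su * np.sqrt(s_post)
    if lfc_threshold < 0:
        raise ValueError("lfc_threshold is a fold change (>= 1) or 0 to disable")
    if lfc_threshold in (0.0, 1.0):
        tau = 0.0
    elif lfc_threshold < 1.0:
        raise ValueError("lfc_threshold is a fold change (>= 1) or 0 to disable")
    else:
        tau = float(np.log2(lfc_threshold))
    tdist = stats.t(df_total) if np.isfinite(df_total) else stats.norm()
    with np.errstate(divide="ignore", invalid="ignore"):
        if tau > 0:
            t_right = (np.abs(beta) - tau) / se
            t_left = (np.abs(beta) + tau) / se
            p = tdist.sf(t_right) + tdist.sf(t_left)
            tstat = np.sign(beta) * t_right
        else:
            tstat = beta / se
            p = 2.0 * tdist.sf(np.abs(tstat))
    # degenerate genes (zero residual variance everywhere): an effect beyond
    # the threshold is certain, no effect gives p = 1
    zero_se = se == 0
    if zero_se.any():
        beyond = np.abs(beta) > tau
        p = np.where(zero_se, np.where(beyond, 0.0, 1.0), p)
        tstat = np.where(zero_se & ~beyond, 0.0, tstat)
    p = np.clip(p, 0.0, 1.0)
    table = pd.DataFrame(
        {
            "logFC": beta,
            "t": tstat,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=fit.coefficients.index,
    )
    return ModeratedResult(
        table=table, d0=float(d0), s0_sq=float(s0_sq), lfc_threshold=tau, target=target
    )


def bh_adjust(p: ArrayLike) -> NDArray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Sliding-window scan


@dataclass
class WindowScanResult:
    """Per-window counts and per-phase unique significant gene sets."""

    windows: pd.DataFrame  # start, ranks, boundary percentage, phase, n significant
    genes_by_phase: dict[str, set] = field(default_factory=dict)
    genes_by_window: list[pd.Index] = field(default_factory=list)
    window_size: int = 8

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def unique_significant(self) -> set:
        out = set()
        for s in self.genes_by_phase.values():
            out |= s
        return out


def sliding_window_scan(
    em: pd.DataFrame,
    order: pd.Index | ArrayLike,
    percentages: pd.Series | None = None,
    window: int = 8,
    lfc_threshold: float = 1.2,
    alpha: float = 0.05,
    boundaries: tuple[float, float] = DEFAULT_PHASE_BOUNDARIES,
) -> WindowScanResult:
    """Scan the cycle ordering for genes changing within a short span.

    Samples ranked by ``order`` are compared two-group — ranks
    [i, i+window) versus [i+window, i+2*window) for every start i — with a
    moderated treat test at the fold-change threshold and BH correction
    within each window.  Each window is attributed the percentage midpoint
    between its two blocks (read off ``percentages`` when supplied, else
    the rank midpoint scaled to 0–100) and pooled per phase.
    """
    if window < 2:
        raise ValueError("window size must be >= 2")
    order = pd.Index(order)
    n = len(order)
    if n < 2 * window:
        raise ValueError(f"need at least {2 * window} samples, got {n}")
    X = np.zeros((2 * window, 2))
    X[:, 0] = 1.0
    X[window:, 1] = 1.0
    design_cols = ["intercept", "group2_vs_1"]
    rows = []
    genes_by_window: list[pd.Index] = []
    genes_by_phase: dict[str, set] = {"menstrual": set(), "proliferative": set(), "secretory": set()}
    for start in range(n - 2 * window + 1):
        ids = order[start : start + 2 * window]
        sub = em[ids]
        dm = DesignMatrix(pd.DataFrame(X, index=ids, columns=design_cols), target="group2_vs_1")
        fit = fit_genewise(sub, dm)
        res = ebayes_moderate(fit, lfc_threshold=lfc_threshold)
        sig = res.table.index[res.table["p_adj"] < alpha]
        left_last, right_first = order[start + window - 1], order[start + window]
        if percentages is not None:
            pct = float((percentages[left_last] + percentages[right_first]) / 2.0)
        else:
            pct = 100.0 * (start + window) / n
        phase = str(phase_of(min(pct, 100.0 - 1e-9), boundaries))
        genes_by_phase[phase] |= set(sig)
        genes_by_window.append(sig)
        rows.append(
            {
                "start_rank": start + 1,
                "boundary_pct": pct,
                "phase": phase,
                "n_significant": len(sig),
            }
        )
    return WindowScanResult(
        windows=pd.DataFrame(rows),
        genes_by_phase=genes_by_phase,
        genes_by_window=genes_by_window,
        window_size=window,
    )


# ---------------------------------------------------------------------------
# Weighted Fisher meta-analysis


def wfisher_meta(
    p_lists: ArrayLike,
    n_samples: ArrayLike,
    gene_ids=None,
) -> pd.Series:
    """Combine per-study p-values with the weighted Fisher method.

    ``p_lists`` is (n_studies x n_genes).  Study i receives weight
    w_i = k * n_i / sum(n) (weights sum to the number of studies k); its
    p-value maps to the upper Gamma(w_i, scale=2) quantile, the sum is
    referred to the Gamma(k, scale=2) upper tail.  Equal weights recover
    classical Fisher; a single study returns its p-values unchanged.
    """
    P = np.atleast_2d(np.asarray(p_lists, dtype=float))
    n_samples = np.asarray(n_samples, dtype=float)
    k = P.shape[0]
    if len(n_samples) != k:
        raise ValueError("one sample size per study required")
    if np.any(P > 1) or np.any(P < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(P == 0):
        import warnings

        warnings.warn("zero p-values clamped to the smallest positive float")
        P = np.maximum(P, np.finfo(float).tiny)
    w = k * n_samples / n_samples.sum()
    Xs = np.vstack([stats.gamma.isf(P[i], a=w[i], scale=2.0) for i in range(k)])
    T = Xs.sum(axis=0)
    combined = stats.gamma.sf(T, a=k, scale=2.0)
    return pd.Series(combined, index=gene_ids, name="p_combined")


def rapid_gene_overlap(
    scan: WindowScanResult,
    reference: ArrayLike,
    matrix_genes: ArrayLike,
    window_pct: tuple[float, float] = (64.0, 78.0),
) -> dict:
    """Overlap of scan hits inside a cycle window with a reference list.

    A gene counts as rapidly changing if it is significant in any window
    whose comparison boundary falls inside ``window_pct``.  The reference is
    matched against the matrix genes first; no overlap is an error.
    """
    reference = list(dict.fromkeys(reference))
    if not reference:
        raise ValueError("empty reference gene list")
    matrix_genes = set(matrix_genes)
    matched = [g for g in reference if g in matrix_genes]
    if not matched:
        raise ValueError("no reference genes present in the matrix")
    lo, hi = window_pct
    hits: set = set()
    for sig, pct in zip(scan.genes_by_window, scan.windows["boundary_pct"]):
        if lo <= pct <= hi:
            hits |= set(sig)
    overlap = [g for g in matched if g in hits]
    return {
        "n_reference": len(reference),
        "n_matched": len(matched),
        "n_overlap": len(overlap),
        "fraction": len(overlap) / len(matched),
        "overlap_genes": overlap,
    }
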
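"""Penalized cubic and cyclic-cubic regression splines.

The staging model needs, for every gene, a smooth curve f_g(t) of expression
against a (possibly circular) time axis.  Curves are cubic regression splines
in the cardinal parameterization: the coefficients are the function values at
the knots, and the second derivatives at the knots follow from the standard
tridiagonal interpolation conditions.  The roughness penalty is the exact
integrated squared second derivative of the interpolating spline, so

    minimize  ||y - X beta||^2 + lambda * beta' S beta

with S the penalty matrix induced by that construction.  A cyclic basis
identifies the two ends of the period (value and first/second derivative
continuous across the seam); its penalty null space is the constants, while
the non-cyclic (natural) penalty null space is the linear functions.

The smoothing parameter is selected per curve by generalized cross-validation
over a fixed log-spaced grid, which keeps fitting deterministic and cheap to
vectorize across tens of thousands of genes that share one design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "SplineSpec",
    "SplineBasis",
    "GeneCurve",
    "CurveSet",
    "PenalizedSplineSmoother",
    "fit_penalized_spline",
    "predict_curve",
    "fit_curve_set",
    "default_lambda_grid",
]


def default_lambda_grid(n: int = 41, low: float = 1e-4, high: float = 1e6) -> NDArray:
    """Log-spaced smoothing-parameter grid used for GCV selection."""
    return np.logspace(np.log10(low), np.log10(high), n)


@dataclass(frozen=True)
class SplineSpec:
    """Shared description of a spline basis.

    Parameters
    ----------
    k:
        Basis dimension (number of knots).  A cyclic basis with ``k`` knots
        has ``k - 1`` free coefficients because the seam knot is identified
        with the first knot.
    cyclic:
        Whether the curve is periodic over the domain.
    domain:
        ``(t_min, t_max)``; for a cyclic spec the period equals the domain
        length and ``t_max`` is identified with ``t_min``.
    """

    k: int
    cyclic: bool
    domain: tuple[float, float]

    def __post_init__(self):
        if self.k < 3:
            raise ValueError(f"basis dimension k must be >= 3, got {self.k}")
        if not self.domain[1] > self.domain[0]:
            raise ValueError(f"domain must satisfy t_max > t_min, got {self.domain}")

    @property
    def period(self) -> float:
        return self.domain[1] - self.domain[0]

    @property
    def n_coef(self) -> int:
        return self.k - 1 if self.cyclic else self.k


def _natural_matrices(knots: NDArray) -> tuple[NDArray, NDArray]:
    """F (k x k, maps knot values to knot second derivatives) and penalty S
    for a natural cubic spline with the given interior structure."""
    k = len(knots)
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    BinvD = np.linalg.solve(B, D)
    F = np.zeros((k, k))
    F[1:-1] = BinvD  # natural conditions: zero curvature at the end knots
    S = D.T @ BinvD
    return F, S


def _cyclic_matrices(knots: NDArray) -> tuple[NDArray, NDArray]:
    """As `_natural_matrices` but with the seam knot identified with the
    first knot; both matrices are (k-1) x (k-1)."""
    p = len(knots) - 1
    h = np.diff(knots)  # h[j] = knots[j+1]-knots[j], j = 0..p-1
    B = np.zeros((p, p))
    D = np.zeros((p, p))
    for i in range(p):
        im = (i - 1) % p
        B[i, i] += (h[im] + h[i]) / 3.0
        B[i, (i + 1) % p] += h[i] / 6.0
        B[i, im] += h[im] / 6.0
        D[i, i] += -1.0 / h[im] - 1.0 / h[i]
        D[i, (i + 1) % p] += 1.0 / h[i]
        D[i, im] += 1.0 / h[im]
    BinvD = np.linalg.solve(B, D)
    S = D.T @ BinvD
    return BinvD, S


class SplineBasis:
    """Design and penalty matrices for one `SplineSpec` with fixed knots."""

    def __init__(self, spec: SplineSpec, knots: ArrayLike):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or len(knots) != spec.k:
            raise ValueError(f"expected {spec.k} knots, got shape {knots.shape}")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.spec = spec
        self.knots = knots
        if spec.cyclic:
            if not np.isclose(knots[-1] - knots[0], spec.period):
                raise ValueError("cyclic knots must span exactly one period")
            self.F, self.S = _cyclic_matrices(knots)
        else:
            self.F, self.S = _natural_matrices(knots)

    @classmethod
    def from_times(cls, t: ArrayLike, spec: SplineSpec) -> "SplineBasis":
        """Place knots for the observed design points.

        Non-cyclic: quantiles of the distinct times with the end knots
        clamped to the domain endpoints (so the whole stated domain is
        covered even when the data sit strictly inside it).  Cyclic: knots
        uniform over the period, which stays well-defined when the time axis
        has only a handful of distinct values (e.g. integer stage labels).
        """
        t = np.asarray(t, dtype=float)
        lo, hi = spec.domain
        if spec.cyclic:
            knots = np.linspace(lo, hi, spec.k)
        else:
            uniq = np.unique(t)
            knots = np.quantile(uniq, np.linspace(0, 1, spec.k))
            knots[0], knots[-1] = lo, hi
            if np.any(np.diff(knots) <= 0):  # too few distinct values
                knots = np.linspace(lo, hi, spec.k)
        return cls(spec, knots)

    def _locate(self, t: ArrayLike) -> tuple[NDArray, NDArray]:
        spec = self.spec
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite time values")
        if spec.cyclic:
            t = self.knots[0] + np.mod(t - self.knots[0], spec.period)
        else:
            eps = 1e-9 * max(1.0, abs(spec.domain[0]), abs(spec.domain[1]))
            if np.any(t < spec.domain[0] - eps) or np.any(t > spec.domain[1] + eps):
                raise ValueError(
                    "query outside the non-cyclic domain "
                    f"[{spec.domain[0]}, {spec.domain[1]}]; no extrapolation"
                )
            t = np.clip(t, self.knots[0], self.knots[-1])
        j = np.searchsorted(self.knots, t, side="right") - 1
        j = np.clip(j, 0, len(self.knots) - 2)
        return t, j

    def design(self, t: ArrayLike) -> NDArray:
        """Evaluate the basis: rows map coefficients to f(t_i)."""
        t, j = self._locate(t)
        k = len(self.knots)
        p = self.spec.n_coef
        h = self.knots[j + 1] - self.knots[j]
        xm = t - self.knots[j]
        xp = self.knots[j + 1] - t
        am, ap = xp / h, xm / h
        cm = (xp**3 / h - h * xp) / 6.0
        cp = (xm**3 / h - h * xm) / 6.0
        jl = j % p if self.spec.cyclic else j
        jr = (j + 1) % p if self.spec.cyclic else j + 1
        X = cm[:, None] * self.F[jl] + cp[:, None] * self.F[jr]
        rows = np.arange(len(t))
        X[rows, jl] += am
        X[rows, jr] += ap
        return X


# ---------------------------------------------------------------------------
# Fitting


def _fit_matrix(
    X: NDArray,
    S: NDArray,
    Y: NDArray,
    lambdas: NDArray,
) -> tuple[NDArray, NDArray, NDArray, NDArray]:
    """Penalized least squares for many response columns sharing one design.

    Returns (coef p x G, lambda G, edf G, rss G) with the per-column GCV
    optimum; ties on the GCV score keep the smallest lambda (first grid hit),
    so refitting is bit-identical.
    """
    n, p = X.shape
    XtX = X.T @ X
    XtY = X.T @ Y
    G = Y.shape[1]
    best_gcv = np.full(G, np.inf)
    best_coef = np.zeros((p, G))
    best_lam = np.zeros(G)
    best_edf = np.zeros(G)
    best_rss = np.zeros(G)
    for lam in lambdas:
        A = XtX + lam * S
        try:
            c, low = cho_factor(A)
            coef = cho_solve((c, low), XtY)
            edf = float(np.trace(cho_solve((c, low), XtX)))
        except np.linalg.LinAlgError:
            Ai = np.linalg.pinv(A)
            coef = Ai @ XtY
            edf = float(np.trace(Ai @ XtX))
        resid = Y - X @ coef
        rss = np.einsum("ij,ij->j", resid, resid)
        denom = n - edf
        if denom <= 1e-8:
            if len(lambdas) > 1:
                continue
            gcv = rss.astype(float)  # saturated fit explicitly requested
        else:
            gcv = n * rss / denom**2
        thresh = np.where(
            np.isfinite(best_gcv),
            best_gcv - 1e-12 * (1.0 + np.where(np.isfinite(best_gcv), np.abs(best_gcv), 0.0)),
            np.inf,
        )
        better = gcv < thresh
        if np.any(better):
            best_gcv[better] = gcv[better]
            best_coef[:, better] = coef[:, better]
            best_lam[better] = lam
            best_edf[better] = edf
            best_rss[better] = rss[better]
    if np.any(~np.isfinite(best_gcv)):
        raise ValueError("GCV failed for every smoothing parameter")
    return best_coef, best_lam, best_edf, best_rss


def _adj_r2(rss: NDArray, tss: NDArray, n: int, edf: NDArray, y_scale: NDArray) -> NDArray:
    """1 - (RSS/(n-edf)) / (TSS/(n-1)), clipped at 0; defined as 0 when the
    response is constant (TSS = 0 up to float rounding)."""
    denom = np.maximum(n - edf, 1e-8)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 - (rss / denom) / (tss / (n - 1))
    constant = tss <= n * (1e-10 * (1.0 + y_scale)) ** 2
    out = np.where(constant, 0.0, out)
    return np.clip(out, 0.0, 1.0)


@dataclass
class GeneCurve:
    """One fitted penalized-spline expression curve."""

    gene_id: str
    spec: SplineSpec
    knots: NDArray
    coefficients: NDArray
    smoothing_lambda: float
    effective_df: float
    adj_r2: float
    residual_sd: float

    def predict(self, t: ArrayLike) -> NDArray:
        return SplineBasis(self.spec, self.knots).design(t) @ self.coefficients


@dataclass
class CurveSet:
    """Per-gene curves sharing one spec and knot vector.

    ``coef`` is (n_coef x n_genes); per-gene smoothing parameters, effective
    degrees of freedom and fit statistics are stored alongside.
    """

    spec: SplineSpec
    knots: NDArray
    gene_ids: list[str]
    coef: NDArray
    smoothing_lambda: NDArray
    effective_df: NDArray
    adj_r2: NDArray
    residual_sd: NDArray
    _basis: SplineBasis | None = field(default=None, repr=False, compare=False)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def basis(self) -> SplineBasis:
        if self._basis is None:
            self._basis = SplineBasis(self.spec, self.knots)
        return self._basis

    def predict(self, t: ArrayLike) -> NDArray:
        """Curve values at `t`: array (len(t), n_genes)."""
        return self.basis().design(t) @ self.coef

    def curve(self, gene_id: str) -> GeneCurve:
        i = self.gene_ids.index(gene_id)
        return GeneCurve(
            gene_id,
            self.spec,
            self.knots,
            self.coef[:, i].copy(),
            float(self.smoothing_lambda[i]),
            float(self.effective_df[i]),
            float(self.adj_r2[i]),
            float(self.residual_sd[i]),
        )

    def subset(self, gene_ids: Sequence[str]) -> "CurveSet":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return CurveSet(
            self.spec,
            self.knots,
            list(gene_ids),
            self.coef[:, idx],
            self.smoothing_lambda[idx],
            self.effective_df[idx],
            self.adj_r2[idx],
            self.residual_sd[idx],
        )

    # -- JSON round trip -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "spec": {
                "k": self.spec.k,
                "cyclic": self.spec.cyclic,
                "domain": list(self.spec.domain),
            },
            "knots": self.knots.tolist(),
            "gene_ids": list(self.gene_ids),
            "coef": self.coef.tolist(),
            "smoothing_lambda": self.smoothing_lambda.tolist(),
            "effective_df": self.effective_df.tolist(),
            "adj_r2": self.adj_r2.tolist(),
            "residual_sd": self.residual_sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CurveSet":
        spec = SplineSpec(
            k=int(d["spec"]["k"]),
            cyclic=bool(d["spec"]["cyclic"]),
            domain=tuple(d["spec"]["domain"]),
        )
        return cls(
            spec,
            np.asarray(d["knots"], dtype=float),
            list(d["gene_ids"]),
            np.asarray(d["coef"], dtype=float),
            np.asarray(d["smoothing_lambda"], dtype=float),
            np.asarray(d["effective_df"], dtype=float),
            np.asarray(d["adj_r2"], dtype=float),
            np.asarray(d["residual_sd"], dtype=float),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "CurveSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_fit_inputs(t: NDArray, Y: NDArray, spec: SplineSpec) -> None:
    if len(t) != Y.shape[0]:
        raise ValueError("times and responses differ in length")
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite expression values")
    n_distinct = len(np.unique(np.mod(t - spec.domain[0], spec.period) if spec.cyclic else t))
    if n_distinct < spec.n_coef:
        raise ValueError(
            f"need >= {spec.n_coef} distinct design points for this basis, "
            f"got {n_distinct}"
        )


def fit_curve_matrix(
    t: ArrayLike,
    Y: ArrayLike,
    spec: SplineSpec,
    gene_ids: Sequence[str],
    lambdas: ArrayLike | None = None,
    knots: ArrayLike | None = None,
) -> CurveSet:
    """Fit one penalized spline per column of ``Y`` (n_samples x n_genes)."""
    t = np.asarray(t, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    _check_fit_inputs(t, Y, spec)
    lambdas = default_lambda_grid() if lambdas is None else np.asarray(lambdas, float)
    basis = (
        SplineBasis(spec, knots) if knots is not None else SplineBasis.from_times(t, spec)
    )
    X = basis.design(t)
    coef, lam, edf, rss = _fit_matrix(X, basis.S, Y, lambdas)
    n = len(t)
    tss = np.einsum("ij,ij->j", Y - Y.mean(axis=0), Y - Y.mean(axis=0))
    adj = _adj_r2(rss, tss, n, edf, np.abs(Y).max(axis=0))
    resid_sd = np.sqrt(rss / np.maximum(n - edf, 1.0))
    return CurveSet(spec, basis.knots, list(gene_ids), coef, lam, edf, adj, resid_sd)


def fit_penalized_spline(
    t: ArrayLike,
    y: ArrayLike,
    spec: SplineSpec,
    gene_id: str = "gene",
    lambdas: ArrayLike | None = None,
    knots: ArrayLike | None = None,
) -> GeneCurve:
    """Fit a single curve; see `fit_curve_matrix` for the contract."""
    cs = fit_curve_matrix(t, np.asarray(y, float)[:, None], spec, [gene_id], lambdas, knots)
    return cs.curve(gene_id)


def predict_curve(curve: GeneCurve, t_query: ArrayLike) -> NDArray:
    """Evaluate a fitted curve; cyclic queries wrap modulo the period and
    non-cyclic queries outside the domain raise."""
    return curve.predict(t_query)


def fit_curve_set(em, t: ArrayLike, spec: SplineSpec, lambdas=None) -> CurveSet:
    """Fit every gene of an expression matrix (genes x samples DataFrame)
    against per-sample times."""
    t = np.asarray(t, dtype=float)
    if em.shape[1] != len(t):
        raise ValueError("one time per sample required")
    return fit_curve_matrix(t, em.to_numpy().T, spec, list(em.index), lambdas)


class PenalizedSplineSmoother(BaseEstimator, RegressorMixin):
    """Scikit-learn style wrapper around one penalized regression spline.

    Parameters
    ----------
    k : basis dimension (number of knots).
    cyclic : periodic basis if True.
    domain : ``(t_min, t_max)``; inferred from the data when None.
    lambdas : smoothing-parameter grid for GCV; default `default_lambda_grid`.
    """

    def __init__(self, k=8, cyclic=False, domain=None, lambdas=None):
        self.k = k
        self.cyclic = cyclic
        self.domain = domain
        self.lambdas = lambdas

    def _spec(self, t: NDArray) -> SplineSpec:
        domain = self.domain
        if domain is None:
            domain = (float(np.min(t)), float(np.max(t)))
        return SplineSpec(k=self.k, cyclic=self.cyclic, domain=tuple(domain))

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        spec = self._spec(t)
        self.curve_ = fit_penalized_spline(t, y, spec, lambdas=self.lambdas)
        self.spec_ = spec
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.curve_.predict(t)
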
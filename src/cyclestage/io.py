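"""Reading, writing and preprocessing of expression matrices.

Conventions used throughout the package:

* expression and count matrices are :class:`pandas.DataFrame` with genes (or
  probes) as rows — the index is named ``gene_id`` — and samples as columns;
* sample annotations are a DataFrame indexed by ``sample_id`` with columns
  ``stage`` (integer 1–7), ``pod_1``/``pod_2``/... (per-pathologist
  post-ovulatory day estimates), ``age``, ``group`` and ``batch``, all
  optional except the ones a given workflow needs;
* gene lists are plain text, one identifier per line.

Count preprocessing follows the usual RNA-seq route: drop genes expressed at
trivially low levels (CPM below a cutoff in more than a stated fraction of
samples, computed on raw library sizes because filtering precedes
normalization), then TMM between-sample normalization and a log2-CPM
transform with a library-size-scaled prior count.  Array data are accepted
as already-normalized log2 intensities; probe-level rows are collapsed to
genes by keeping, per gene, the probe with the greatest mean expression.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_annotation",
    "write_annotation",
    "read_gene_list",
    "write_gene_list",
    "validate_counts",
    "filter_low_expression",
    "tmm_factors",
    "tmm_log2cpm",
    "collapse_probes",
    "detection_filter",
    "pod_columns",
    "pod_estimates",
]

ANNOTATION_COLUMNS = ("stage", "age", "group", "batch")


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_table(path, value_kind: str = "log2", orientation: str = "genes_by_samples") -> pd.DataFrame:
    """Read a delimited gene x sample matrix.

    ``value_kind`` is ``"counts"`` (non-negative integers) or ``"log2"``
    (real log2 expression).  Duplicated row or column identifiers, ragged
    rows and non-numeric cells raise with the offending labels.
    """
    if value_kind not in ("counts", "log2"):
        raise ValueError(f"value_kind must be 'counts' or 'log2', got {value_kind!r}")
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
    if orientation == "samples_by_genes":
        df = df.T
    elif orientation != "genes_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    dup_rows = df.index[df.index.duplicated()].unique().tolist()
    if dup_rows:
        raise ValueError(f"duplicated gene identifiers: {dup_rows}")
    dup_cols = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_cols:
        raise ValueError(f"duplicated sample identifiers: {dup_cols}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        nn = bad.isna() & df[col].notna()
        if nn.any():
            raise ValueError(
                f"non-numeric value in column {col!r}, rows {df.index[nn].tolist()[:5]}"
            )
        df[col] = bad
    if df.isna().any().any():
        raise ValueError("missing values in expression table")
    df = df.astype(float)
    if value_kind == "counts":
        validate_counts(df)
    else:
        if not np.all(np.isfinite(df.to_numpy())):
            raise ValueError("non-finite expression values")
    df.index.name = "gene_id"
    return df


def validate_counts(counts: pd.DataFrame) -> None:
    vals = counts.to_numpy()
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite count values")
    if (vals < 0).any():
        bad = counts.index[(vals < 0).any(axis=1)].tolist()[:5]
        raise ValueError(f"negative counts for genes {bad}")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("counts must be integers")


def write_expression_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=_sep_for(path))


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    ann.index.name = "sample_id"
    dup = ann.index[ann.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicated sample identifiers: {dup}")
    if "stage" in ann.columns:
        stages = ann["stage"].dropna()
        bad = stages[~stages.isin(range(1, 8))]
        if len(bad):
            raise ValueError(f"stage labels outside 1..7 for samples {bad.index.tolist()[:5]}")
    for col in pod_columns(ann):
        pods = ann[col].dropna()
        if ((pods < 1) | (pods > 14)).any():
            raise ValueError(f"POD estimates outside [1, 14] in column {col!r}")
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep_for(path))


def pod_columns(ann: pd.DataFrame) -> list[str]:
    return [c for c in ann.columns if c.startswith("pod")]


def pod_estimates(ann: pd.DataFrame) -> pd.DataFrame:
    """Per-pathologist POD calls as a samples x raters frame (NaN = no call)."""
    cols = pod_columns(ann)
    return ann[cols].astype(float) if cols else pd.DataFrame(index=ann.index)


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# Count preprocessing


def filter_low_expression(
    counts: pd.DataFrame, cpm_threshold: float = 0.5, sample_fraction: float = 0.8
) -> pd.DataFrame:
    """Remove genes with CPM below ``cpm_threshold`` in strictly more than
    ``sample_fraction`` of the samples.

    CPM uses raw library sizes (column sums): filtering precedes
    normalization.  The inequality is strict — a gene low in exactly 80% of
    samples is kept under the defaults.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("library size of zero; cannot compute CPM")
    cpm = counts.to_numpy(dtype=float) / lib * 1e6
    n_low = (cpm < cpm_threshold).sum(axis=1)
    keep = n_low <= sample_fraction * counts.shape[1]
    if not keep.any():
        raise ValueError(
            "all genes removed by the low-expression filter; review cpm_threshold"
        )
    return counts.loc[keep]


def _quantile_reference(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> int:
    uq = np.quantile(counts / lib, p, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """TMM scaling factor of one sample against the reference column."""
    po, pr = obs / lib_obs, ref / lib_ref
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2(po / pr)
        a = 0.5 * np.log2(po * pr)
        # inverse asymptotic variance of M on relative proportions (nominal
        # per-million library), keeping the transform exactly scale-free
        w = (1.0 - po) / (1e6 * po) + (1.0 - pr) / (1e6 * pr)
    ok = np.isfinite(m) & np.isfinite(a) & (a > -1e10)  # zero counts drop out
    m, a, w = m[ok], a[ok], w[ok]
    if len(m) == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:  # identical relative profiles
        return 1.0
    n = len(m)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    # ranks 1..n with average ties, as in the published procedure
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3, sum_trim: float = 0.05) -> pd.Series:
    """Per-sample TMM scaling factors, normalized to geometric mean 1.

    Reference sample: upper quartile of CPM closest to the mean upper
    quartile.  M-values trimmed 30% from each tail and A-values 5%; genes
    with a zero count in either sample are excluded; the trimmed mean is
    weighted by inverse asymptotic variances.
    """
    vals = counts.to_numpy(dtype=float)
    lib = vals.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples {bad}")
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    ref = _quantile_reference(vals, lib)
    f = np.array(
        [
            _tmm_pair(vals[:, j], vals[:, ref], lib[j], lib[ref], logratio_trim, sum_trim)
            for j in range(vals.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


def tmm_log2cpm(counts: pd.DataFrame, prior_count: float = 2.0) -> pd.DataFrame:
    """TMM-normalized log2-CPM.

    The effective library size is the raw library size times the TMM factor.
    The prior count is scaled per sample proportionally to the effective
    library size (in per-million units), which makes the transform exactly
    invariant to rescaling any single sample's counts.
    """
    validate_counts(counts)
    f = tmm_factors(counts)
    lib_eff = counts.sum(axis=0).to_numpy(dtype=float) * f.to_numpy()
    prior = prior_count * lib_eff / 1e6
    vals = counts.to_numpy(dtype=float)
    log2cpm = np.log2((vals + prior) / (lib_eff + 2.0 * prior) * 1e6)
    out = pd.DataFrame(log2cpm, index=counts.index, columns=counts.columns)
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# Array probes


def detection_filter(
    em: pd.DataFrame, detection_p: pd.DataFrame, alpha: float = 0.05, min_fraction: float = 0.2
) -> pd.DataFrame:
    """Keep probes detected (p < alpha) in at least ``min_fraction`` of samples."""
    dp = detection_p.loc[em.index, em.columns]
    keep = (dp.to_numpy() < alpha).mean(axis=1) >= min_fraction
    return em.loc[keep]


def collapse_probes(
    em: pd.DataFrame,
    probe_map: pd.DataFrame,
    allowed_quality: Sequence[str] = ("Good", "Perfect"),
) -> pd.DataFrame:
    """Collapse a probe-level matrix to genes.

    ``probe_map`` has columns ``probe_id``, ``gene_id`` and optionally
    ``quality``; probes failing the quality filter are dropped, and for each
    gene the probe with the greatest mean expression is kept (ties keep the
    probe appearing first in the input matrix).
    """
    pm = probe_map.copy()
    if "probe_id" not in pm.columns or "gene_id" not in pm.columns:
        raise ValueError("probe map needs 'probe_id' and 'gene_id' columns")
    if pm["probe_id"].duplicated().any():
        dups = pm.loc[pm["probe_id"].duplicated(), "probe_id"].tolist()[:5]
        raise ValueError(f"duplicated probe identifiers in map: {dups}")
    if "quality" in pm.columns and allowed_quality is not None:
        pm = pm[pm["quality"].isin(list(allowed_quality))]
    pm = pm[pm["probe_id"].isin(em.index)]
    if pm.empty:
        raise ValueError("no overlap between matrix probes and the probe map")
    # tie-break on mean expression follows the probe's position in the matrix
    pos = pd.Series(np.arange(em.shape[0]), index=em.index)
    pm = pm.iloc[np.argsort(pos[pm["probe_id"]].to_numpy(), kind="stable")]
    sub = em.loc[pm["probe_id"]]
    means = sub.mean(axis=1).to_numpy()
    order = np.arange(len(pm))  # input order for the tie-break
    pick = (
        pd.DataFrame({"gene_id": pm["gene_id"].to_numpy(), "mean": means, "order": order})
        .sort_values(["gene_id", "mean", "order"], ascending=[True, False, True])
        .drop_duplicates("gene_id", keep="first")
        .sort_values("order")
    )
    out = sub.iloc[pick["order"].to_numpy()].copy()
    out.index = pd.Index(pick["gene_id"].to_numpy(), name="gene_id")
    return out
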
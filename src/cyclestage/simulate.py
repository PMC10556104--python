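"""Seeded generator of cyclic bulk-expression data with known truth.

The generator emulates the statistical structure the staging model assumes:
each sample sits at an unknown true position on a 0–100 cycle (uniformly
distributed, mirroring a cohort sampled at random points of the cycle), and
each gene is either *cyclic* — its mean log2 expression follows a smooth
periodic curve, built from one or two Fourier harmonics with random phases
and a drawn peak-to-trough amplitude — or *flat*.  Observations add Gaussian
log2-scale residual noise.  Harmonic mean curves are deliberately a
different function family from the regression splines used by the fitter,
so recovery tests do not reward shared parameterization.

Coarse labels mimic histopathology: the true percentage is jittered, then
binned into 7 stages (menstrual; early/mid/late proliferative; early/mid/
late secretory), and secretory samples additionally receive two independent
noisy pathologist post-ovulatory-day calls.  Age effects can be injected
into chosen genes confined to a window of the cycle, and a constant batch
shift into a subset of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_cycle",
    "simulate_counts",
    "label_with_pathology",
    "inject_covariate_effects",
    "STAGE_BANDS",
]

#: stage -> half-open band on the true percentage scale
STAGE_BANDS = {
    1: (0.0, 8.0),
    2: (8.0, 8.0 + 50.0 / 3),
    3: (8.0 + 50.0 / 3, 8.0 + 100.0 / 3),
    4: (8.0 + 100.0 / 3, 58.0),
    5: (58.0, 72.0),
    6: (72.0, 86.0),
    7: (86.0, 100.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults define the canonical benchmark cohort."""

    n_samples: int = 120
    n_genes: int = 1500
    frac_cyclic: float = 0.3
    n_harmonics: int = 2
    amplitude_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 0.5
    baseline_range: tuple[float, float] = (4.0, 12.0)
    label_error_sd: float = 4.0
    pod_error_days: float = 1.0
    percentage_range: tuple[float, float] = (0.0, 100.0)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.frac_cyclic <= 1.0:
            raise ValueError("frac_cyclic must be in [0, 1]")
        for name in ("n_samples", "n_genes", "n_harmonics"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("noise_sd", "label_error_sd", "pod_error_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated matrix."""

    config: SimConfig
    true_percentage: pd.Series  # per sample, in [0, 100)
    cyclic: np.ndarray  # bool per gene
    baseline: np.ndarray  # per gene
    amplitude: np.ndarray  # peak-to-trough, 0 for flat genes
    harmonic_amp: np.ndarray  # (n_genes, n_harmonics)
    harmonic_phase: np.ndarray  # (n_genes, n_harmonics)
    gene_ids: list[str] = field(default_factory=list)
    ages: pd.Series | None = None
    age_genes: list[str] = field(default_factory=list)
    age_slopes: dict[str, float] = field(default_factory=dict)
    age_window: tuple[float, float] | None = None
    batch: pd.Series | None = None

    def mean_expression(self, t: np.ndarray) -> np.ndarray:
        """Noise-free mean matrix (n_genes x len(t)) at percentages ``t``."""
        t = np.asarray(t, dtype=float)
        h = np.arange(1, self.config.n_harmonics + 1)
        # (G, H, T)
        phase = 2.0 * np.pi * h[None, :, None] * t[None, None, :] / 100.0
        waves = self.harmonic_amp[:, :, None] * np.cos(
            phase + self.harmonic_phase[:, :, None]
        )
        return self.baseline[:, None] + waves.sum(axis=1)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def simulate_cycle(cfg: SimConfig | None = None, **overrides) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a log2 expression matrix (genes x samples) with known truth.

    Fully deterministic given ``cfg.seed``.  Keyword overrides build a
    modified copy of the default configuration.
    """
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)
    G, n, H = cfg.n_genes, cfg.n_samples, cfg.n_harmonics
    lo, hi = cfg.percentage_range
    t = rng.uniform(lo, hi, size=n)

    n_cyc = round(cfg.frac_cyclic * G)
    cyclic = np.zeros(G, dtype=bool)
    cyclic[rng.permutation(G)[:n_cyc]] = True

    baseline = rng.uniform(*cfg.baseline_range, size=G)
    amplitude = np.zeros(G)
    amplitude[cyclic] = rng.uniform(*cfg.amplitude_range, size=n_cyc)

    # raw harmonic shapes, rescaled so peak-to-trough equals the drawn amplitude
    raw_amp = rng.normal(size=(G, H)) / np.arange(1, H + 1)
    phases = rng.uniform(0, 2 * np.pi, size=(G, H))
    raw_amp[~cyclic] = 0.0
    grid = np.linspace(0, 100, 512, endpoint=False)
    hh = np.arange(1, H + 1)
    wave = (
        raw_amp[:, :, None]
        * np.cos(2 * np.pi * hh[None, :, None] * grid[None, None, :] / 100.0 + phases[:, :, None])
    ).sum(axis=1)
    ptp = wave.max(axis=1) - wave.min(axis=1)
    scale = np.zeros(G)
    nz = ptp > 0
    scale[nz] = amplitude[nz] / ptp[nz]
    harmonic_amp = raw_amp * scale[:, None]

    truth = SyntheticTruth(
        config=cfg,
        true_percentage=pd.Series(t, index=_sample_ids(n), name="true_percentage"),
        cyclic=cyclic,
        baseline=baseline,
        amplitude=amplitude,
        harmonic_amp=harmonic_amp,
        harmonic_phase=phases,
        gene_ids=_gene_ids(G),
    )
    mean = truth.mean_expression(t)
    noise = rng.normal(0.0, cfg.noise_sd, size=(G, n))
    em = pd.DataFrame(mean + noise, index=_gene_ids(G), columns=_sample_ids(n))
    em.index.name = "gene_id"
    return em, truth


def simulate_counts(
    cfg: SimConfig | None = None, mean_library: float = 2e6, **overrides
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Poisson count matrix whose log2-CPM means follow the cyclic curves.

    Exercises the filtering and TMM code paths; library sizes vary around
    ``mean_library``.
    """
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    em, truth = simulate_cycle(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_samples
    lib = rng.uniform(0.6 * mean_library, 1.4 * mean_library, size=n)
    cpm = 2.0 ** truth.mean_expression(truth.true_percentage.to_numpy())
    lam = cpm * lib[None, :] / 1e6
    counts = rng.poisson(lam).astype(float)
    out = pd.DataFrame(counts, index=em.index, columns=em.columns)
    out.index.name = "gene_id"
    return out, truth


def stage_from_percentage(pct: np.ndarray) -> np.ndarray:
    """Map percentages to the 7 coarse stages via the fixed bands."""
    pct = np.mod(np.asarray(pct, dtype=float), 100.0)
    stages = np.empty(len(pct), dtype=int)
    for s, (lo, hi) in STAGE_BANDS.items():
        stages[(pct >= lo) & (pct < hi)] = s
    return stages


def label_with_pathology(
    truth: SyntheticTruth,
    label_error_sd: float | None = None,
    pod_error_days: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emulate pathologist staging of the simulated cohort.

    The true percentage is jittered by Gaussian error (wrapped mod 100) and
    binned into the 7 stages; secretory samples get two independent noisy
    POD calls of ``round(14 * (t' - 58) / 42)`` clipped to [1, 14].
    """
    cfg = truth.config
    sd = cfg.label_error_sd if label_error_sd is None else label_error_sd
    pod_sd = cfg.pod_error_days if pod_error_days is None else pod_error_days
    rng = np.random.default_rng(cfg.seed + 1000 if seed is None else seed)
    t = truth.true_percentage.to_numpy()
    t_jit = np.mod(t + rng.normal(0.0, sd, size=len(t)), 100.0)
    stage = stage_from_percentage(t_jit)
    ann = pd.DataFrame(index=truth.true_percentage.index.copy())
    ann.index.name = "sample_id"
    ann["stage"] = stage
    secretory = stage >= 5
    pod_base = 14.0 * (t_jit - 58.0) / 42.0
    for rater in (1, 2):
        noise = rng.normal(0.0, pod_sd, size=len(t))
        call = np.clip(np.round(pod_base + noise), 1, 14)
        ann[f"pod_{rater}"] = np.where(secretory, call, np.nan)
    if truth.ages is not None:
        ann["age"] = truth.ages
    if truth.batch is not None:
        ann["batch"] = truth.batch
    return ann


def inject_covariate_effects(
    em: pd.DataFrame,
    truth: SyntheticTruth,
    n_age_genes: int,
    slope: float,
    phase_window: tuple[float, float] = (58.0, 100.0),
    batch_shift: float = 0.0,
    batch_fraction: float = 0.5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Add an age effect to chosen genes, confined to a cycle window.

    Ages are drawn uniformly on [20, 49]; for each selected gene,
    ``slope * (age - mean age)`` is added only to samples whose true
    percentage lies in ``phase_window``.  Optionally a constant
    ``batch_shift`` is added to every gene of a designated sample subset.
    Returns the modified matrix and an updated truth object.
    """
    if n_age_genes > truth.config.n_genes:
        raise ValueError("n_age_genes exceeds the number of genes")
    rng = np.random.default_rng(truth.config.seed + 2000 if seed is None else seed)
    out = em.copy()
    n = em.shape[1]
    ages = rng.uniform(20.0, 49.0, size=n)
    centered = ages - ages.mean()
    t = truth.true_percentage.to_numpy()
    in_window = (t >= phase_window[0]) & (t < phase_window[1])
    age_genes = [em.index[i] for i in rng.permutation(em.shape[0])[:n_age_genes]]
    add = slope * centered * in_window
    for g in age_genes:
        out.loc[g] = out.loc[g].to_numpy() + add
    batch = None
    if batch_shift != 0.0:
        n_b = int(round(batch_fraction * n))
        members = np.zeros(n, dtype=bool)
        members[rng.permutation(n)[:n_b]] = True
        out.loc[:, members] = out.loc[:, members] + batch_shift
        batch = pd.Series(np.where(members, "B", "A"), index=em.columns, name="batch")
    new_truth = replace(truth)
    new_truth.ages = pd.Series(ages, index=em.columns, name="age")
    new_truth.age_genes = age_genes
    new_truth.age_slopes = {g: slope for g in age_genes}
    new_truth.age_window = tuple(phase_window)
    new_truth.batch = batch
    return out, new_truth
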
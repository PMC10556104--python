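"""End-to-end staging pipeline and run bundles.

`run_full_pipeline` chains the whole-cycle workflow — proliferative
reassignment, cyclic stage fit, MSE time assignment, uniformization to the
0–100 percentage scale, percentage-axis refit and cycle normalization — and
writes a reusable model bundle: model JSON, assignment and normalized-matrix
TSVs, and a run-metadata manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import write_annotation, write_expression_table
from .staging import (
    DEFAULT_PHASE_BOUNDARIES,
    StagingModel,
    fit_whole_cycle,
    normalize_for_cycle,
    phase_of,
    reassign_proliferative,
    refit_percentage,
    uniformize_times,
)

__all__ = ["PipelineResult", "run_full_pipeline"]


@dataclass
class PipelineResult:
    """In-memory outputs of the whole-cycle pipeline."""

    stage_model: StagingModel
    percentage_model: StagingModel
    annotation: pd.DataFrame
    assignments: pd.DataFrame
    normalized: pd.DataFrame


def _require_columns(ann: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation is missing required columns: {missing}")


def run_full_pipeline(
    em: pd.DataFrame,
    ann: pd.DataFrame,
    out_dir: str | Path | None = None,
    grid_step: float | None = None,
    refit_k: int = 30,
    phase_boundaries: tuple[float, float] = DEFAULT_PHASE_BOUNDARIES,
    seed: int = 0,
    config: dict | None = None,
) -> PipelineResult:
    """Run reassignment -> cyclic fit -> assignment -> uniformization ->
    percentage refit -> normalization; optionally write the bundle.

    The pipeline itself is deterministic; ``seed`` is recorded in the
    manifest for the benefit of stochastic upstream steps (simulation,
    cross-validation) configured by the caller.
    """
    _require_columns(ann, ["stage"])
    try:
        ann2 = reassign_proliferative(em, ann)
    except ValueError as exc:
        raise ValueError(f"proliferative reassignment failed: {exc}") from exc
    try:
        stage_model, assignments = fit_whole_cycle(em, ann2, grid_step=grid_step)
    except ValueError as exc:
        raise ValueError(f"whole-cycle fit failed: {exc}") from exc
    anchor = assignments.loc[
        ann2.index[(ann2["stage"] == 1) & ann2.index.isin(assignments.index)],
        "model_time",
    ].to_numpy()
    assignments = uniformize_times(assignments, period=7.0, anchor_times=anchor)
    curves_pct = refit_percentage(em, assignments["percentage"], k=refit_k)
    normalized = normalize_for_cycle(em, curves_pct, assignments["percentage"])
    assignments["phase"] = phase_of(assignments["percentage"].to_numpy(), phase_boundaries)
    pct_model = StagingModel(
        curves=curves_pct,
        time_axis_kind="percentage_cyclic",
        grid_step=0.05,
        gene_means=em.mean(axis=1),
        phase_boundaries=phase_boundaries,
        training_assignments=assignments,
    )
    result = PipelineResult(
        stage_model=stage_model,
        percentage_model=pct_model,
        annotation=ann2,
        assignments=assignments,
        normalized=normalized,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir), seed=seed, config=config or {})
    return result


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_bundle(result: PipelineResult, out_dir: Path, seed: int, config: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.percentage_model.to_json(out_dir / "staging_model.json")
    assignments = result.assignments.copy()
    assignments.index.name = "sample_id"
    assignments.round(6).to_csv(out_dir / "assignments.tsv", sep="\t")
    write_expression_table(result.normalized.round(6), out_dir / "normalized_matrix.tsv")
    write_annotation(result.annotation, out_dir / "annotation_reassigned.tsv")
    manifest = {
        "tool": "cyclestage",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config": config,
        "config_hash": _config_hash(config),
        "n_samples": int(result.assignments.shape[0]),
        "n_genes": int(result.normalized.shape[0]),
        "outputs": [
            "staging_model.json",
            "assignments.tsv",
            "normalized_matrix.tsv",
            "annotation_reassigned.tsv",
        ],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
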
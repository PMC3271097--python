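"""Null-calibration and power harness for the permutation pipeline.

Runs the full synthetic-data -> preprocessing -> density -> permutation
-> cluster-correction chain under controlled conditions:

* :func:`null_calibration_run` — two conditions drawn from identical
  per-ordinal distributions (the exchangeable null); records whether
  any cluster survives correction (family-wise error) and the fraction
  of face-region pixels declared significant before correction
  (per-pixel error).
* :func:`power_run` — a planted opposite-side shift in one condition's
  fixations 2-5; records whether a surviving cluster of the correct
  sign overlaps the side of the face the shift moved mass to.

Default problem sizes (20 participants, 8 trials per condition, 500
permutations with 125 cluster-null maps on a 0.1 deg/px grid) keep one
run under a couple of seconds so calibration batteries of ~100 seeds
are routine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import GridSpec, align_fixations
from .geometry import Rect, reference_frame
from .inference import PermutationResult, PermutationSpec, run_contrast
from .preprocessing import clamp_to_image, select_first_k
from .synth import (
    GeneratorConfig,
    SyntheticDataset,
    generate_effect_dataset,
    generate_null_dataset,
)

__all__ = [
    "CalibrationSpec",
    "prepare_contrast_data",
    "null_calibration_run",
    "power_run",
    "calibration_battery",
    "power_battery",
    "wilson_interval",
]

#: Reduced-iteration permutation settings for desk-scale calibration.
_DESK_PERMUTATION = PermutationSpec(n_iterations=500, n_cluster_maps=125)


@dataclass(frozen=True)
class CalibrationSpec:
    """Study conditions for one calibration run."""

    n_participants: int = 20
    trials_per_condition: int = 8
    n_faces: int = 16
    grid_cell: float = 0.1
    fixation_range: tuple[int, int] = (2, 5)
    permutation: PermutationSpec = _DESK_PERMUTATION


def prepare_contrast_data(
    dataset: SyntheticDataset, spec: CalibrationSpec
) -> tuple[pd.DataFrame, GridSpec, Rect]:
    bounds = dataset.faces[0].image_bounds
    fix = clamp_to_image(dataset.fixations, bounds)
    lo, hi = spec.fixation_range
    fix = select_first_k(fix, k=hi)
    fix = fix[fix["ordinal"] >= lo]
    reference = reference_frame(dataset.faces)
    fix = align_fixations(fix, dataset.geometries, reference)
    grid = GridSpec.from_bounds(bounds, cell=spec.grid_cell, pad=1.0)
    return fix, grid, bounds


def _run(
    dataset: SyntheticDataset, spec: CalibrationSpec, seed: int
) -> tuple[PermutationResult, GridSpec, Rect]:
    fix, grid, bounds = prepare_contrast_data(dataset, spec)
    result = run_contrast(fix, "left", "right", grid,
                          spec=spec.permutation, seed=seed)
    return result, grid, bounds


def null_calibration_run(
    seed: int, spec: CalibrationSpec | None = None
) -> dict:
    """One exchangeable-null pipeline run.

    Returns ``any_surviving`` (did any cluster survive the
    max-cluster-size correction) and ``sig_fraction`` (fraction of
    pixels inside the face image region with uncorrected p below the
    pixel threshold).
    """
    spec = spec or CalibrationSpec()
    cfg = GeneratorConfig(
        n_participants=spec.n_participants,
        trials_per_cell_study=spec.trials_per_condition,
        n_faces=spec.n_faces,
        seed=seed,
    )
    dataset = generate_null_dataset(cfg)
    result, grid, bounds = _run(dataset, spec, seed)
    face = grid.region_mask(bounds)
    surviving = bool(result.clusters["survives"].any()) \
        if len(result.clusters) else False
    return {
        "any_surviving": surviving,
        "sig_fraction": float(
            (result.pvalues.p < spec.permutation.pixel_alpha)[face].mean()),
        "n_clusters": int(len(result.clusters)),
        "cluster_size_threshold": result.cluster_size_threshold,
    }


def power_run(
    seed: int, delta: float = 1.5, spec: CalibrationSpec | None = None
) -> dict:
    """One planted-effect pipeline run.

    The left-start condition's fixations 2-5 are shifted ``delta``
    degrees toward the right side of the face (the side opposite the
    start). Detection requires a surviving positive cluster (left >
    right) with at least one pixel right of the face midline, i.e. in
    the half of the face the planted mass moved to.
    """
    spec = spec or CalibrationSpec()
    cfg = GeneratorConfig(
        n_participants=spec.n_participants,
        trials_per_cell_study=spec.trials_per_condition,
        n_faces=spec.n_faces,
        seed=seed,
    )
    dataset = generate_effect_dataset(cfg, delta)
    result, grid, bounds = _run(dataset, spec, seed)
    midline_x = 0.5 * (bounds.x_min + bounds.x_max)
    pixel_x = np.tile(grid.x_centers, grid.n_y)
    detected = False
    for row in result.clusters.itertuples():
        if row.survives and row.sign > 0 \
                and (pixel_x[row.pixels] > midline_x).any():
            detected = True
            break
    return {
        "detected": detected,
        "n_surviving": int(result.clusters["survives"].sum())
        if len(result.clusters) else 0,
    }


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def calibration_battery(
    seed: int, n_runs: int = 100, spec: CalibrationSpec | None = None
) -> dict:
    """Independent null runs; summarizes family-wise and per-pixel
    error rates with a Wilson 95% interval on the FWER."""
    results = [null_calibration_run(int(s), spec)
               for s in _sub_seeds(seed, n_runs)]
    n_fp = sum(r["any_surviving"] for r in results)
    lo, hi = wilson_interval(n_fp, n_runs)
    return {
        "n_runs": n_runs,
        "fwer": n_fp / n_runs,
        "fwer_ci": (lo, hi),
        "pixel_error": float(np.mean([r["sig_fraction"] for r in results])),
    }


def power_battery(
    seed: int, n_runs: int = 50, delta: float = 1.5,
    spec: CalibrationSpec | None = None,
) -> dict:
    """Independent planted-effect runs; reports the detection rate."""
    results = [power_run(int(s), delta, spec)
               for s in _sub_seeds(seed, n_runs)]
    return {
        "n_runs": n_runs,
        "delta": delta,
        "detection_rate": float(np.mean([r["detected"] for r in results])),
    }


def wilson_interval(k: int, n: int, z: float = 1.959963984540054):
    """Wilson score 95% interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))
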
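"""Synthetic scanpath and behavior generator.

Emulates the statistical structure of a start-position face-viewing
experiment so the whole analysis pipeline can be calibrated and
power-tested without human data:

* a canonical 7-AOI face layout (10 deg wide), jittered per face to
  stand in for a set of photographs;
* five start positions (left/right/upper/lower/center) derived from
  each face's own AOI geometry;
* the first fixation lands near the face center with a slight bias of
  ``kappa`` degrees *toward* the start position; fixations 2-5 are
  drawn from a landmark-anchored Gaussian mixture (eye-weighted) and
  shifted ``delta`` degrees toward the *opposite* side of the face;
* the first fixation is shorter than later ones; the latency to first
  saccade is longer for the center start position;
* old/new recognition responses follow an equal-variance
  signal-detection model with sensitivity ``dprime_true``.

Trials on inverted faces are generated in the inverted face's own frame
(the geometry is reflected first, then landmarks and start positions
are taken from the reflected face).

One root seed drives everything; per-participant streams are spawned
from it so subsets are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .geometry import (
    AOI_LABELS,
    AoiRect,
    DegenerateGeometryError,
    FaceGeometry,
    InfeasibleDistanceError,
    Rect,
    invert_geometry,
    start_positions,
)
from .preprocessing import REQUIRED_COLUMNS

__all__ = [
    "CANONICAL_LAYOUT",
    "CANONICAL_BOUNDS",
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_faces",
    "generate_trial",
    "generate_dataset",
    "generate_null_dataset",
    "generate_effect_dataset",
    "generate_behavior",
]

#: Canonical AOI rectangles (degrees; origin at face center, y down),
#: sized from a 10-deg forehead width. Declared constants of the
#: generator, not estimates from data.
CANONICAL_LAYOUT: Mapping[str, tuple[float, float, float, float]] = {
    "left_eye": (-2.7, -2.6, -1.1, -1.5),
    "mid_eye": (-0.55, -2.5, 0.55, -1.6),
    "right_eye": (1.1, -2.6, 2.7, -1.5),
    "left_nose": (-1.0, -1.2, 0.0, 0.6),
    "right_nose": (0.0, -1.2, 1.0, 0.6),
    "left_mouth": (-1.7, 1.4, 0.0, 2.4),
    "right_mouth": (0.0, 1.4, 1.7, 2.4),
}
CANONICAL_BOUNDS = Rect(-5.0, -6.0, 5.0, 6.0)

#: Landmark-mixture weights for fixations 2+, favoring the eye region.
DEFAULT_LANDMARK_WEIGHTS: Mapping[str, float] = {
    "left_eye": 0.22, "mid_eye": 0.14, "right_eye": 0.22,
    "left_nose": 0.12, "right_nose": 0.12,
    "left_mouth": 0.09, "right_mouth": 0.09,
}

START_NAMES = ("left", "right", "upper", "lower", "center")

#: Unit vector pointing from the start position toward the opposite
#: side of the face (screen frame, y down).
_OPPOSITE_DIR = {
    "left": (1.0, 0.0), "right": (-1.0, 0.0),
    "upper": (0.0, 1.0), "lower": (0.0, -1.0),
    "center": (0.0, 0.0),
}

_SACCADE_GAP_MS = 25.0  # nominal saccade flight time between fixations


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic experiment."""

    n_participants: int = 20
    n_faces: int = 80
    trials_per_cell_study: int = 4   # per orientation x start cell
    trials_per_cell_test: int = 8
    orientations: tuple[str, ...] = ("upright", "inverted")
    starts: tuple[str, ...] = START_NAMES
    phases: tuple[str, ...] = ("study", "test")

    jitter_sd: float = 0.15          # deg, per-AOI translation jitter

    # fixation location model
    first_fix_sigma: float = 0.7     # deg, around face center
    kappa: float = 0.5               # deg, ordinal-1 bias toward the start
    landmark_sigma: float = 0.8      # deg, mixture component sd
    landmark_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LANDMARK_WEIGHTS))
    delta: float = 1.5               # deg, ordinals 2-5 opposite-side shift

    # fixation count model: min + (truncated geometric), capped at 10
    min_fixations_study: int = 5
    min_fixations_test: int = 3
    max_fixations: int = 10
    extra_fix_p: float = 0.45

    # duration model (ms) by ordinal (last entry reused beyond 5)
    duration_means_ms: tuple[float, ...] = (150.0, 280.0, 300.0, 310.0, 310.0)
    duration_sd_ms: float = 60.0
    min_duration_ms: float = 30.0

    # latency-to-first-saccade model (ms)
    latency_mean_ms: float = 180.0
    latency_center_mean_ms: float = 280.0
    latency_sd_ms: float = 40.0
    latency_center_sd_ms: float = 60.0
    min_latency_ms: float = 80.0

    # behavior model
    dprime_true: float = 2.0
    dprime_true_inverted: float = 1.2
    rt_median_ms: float = 900.0
    rt_log_sd: float = 0.3

    seed: int = 0

    def __post_init__(self) -> None:
        w = self.landmark_weights
        if set(w) != set(AOI_LABELS):
            raise ValueError("landmark_weights must cover exactly the 7 AOIs")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("landmark_weights must sum to 1")
        for name in ("jitter_sd", "first_fix_sigma", "landmark_sigma",
                     "duration_sd_ms", "latency_sd_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SyntheticDataset:
    """Fixation report + per-face geometry + behavioral responses."""

    fixations: pd.DataFrame
    faces: list[FaceGeometry]
    behavior: pd.DataFrame | None
    config: GeneratorConfig

    @property
    def geometries(self) -> dict[str, FaceGeometry]:
        return {f.face_id: f for f in self.faces}


# ---------------------------------------------------------------------------
# faces


def generate_faces(
    config: GeneratorConfig, rng: np.random.Generator, max_retries: int = 50
) -> list[FaceGeometry]:
    """Jittered copies of the canonical layout, one per face.

    Each AOI rectangle is translated by i.i.d. N(0, jitter_sd^2) per
    axis (shape preserved, so rectangles stay valid). Layouts whose
    start positions are unsolvable are resampled a bounded number of
    times before raising.
    """
    faces = []
    for i in range(config.n_faces):
        face_id = f"face{i:03d}"
        for attempt in range(max_retries + 1):
            aois = {}
            for lab, (x0, y0, x1, y1) in CANONICAL_LAYOUT.items():
                dx, dy = rng.normal(0.0, config.jitter_sd, size=2)
                aois[lab] = AoiRect(x0 + dx, y0 + dy, x1 + dx, y1 + dy,
                                    label=lab)
            try:
                face = FaceGeometry(face_id, aois, CANONICAL_BOUNDS, "upright")
                start_positions(face)  # solvability check
            except (DegenerateGeometryError, InfeasibleDistanceError, ValueError):
                if attempt == max_retries:
                    raise DegenerateGeometryError(
                        f"could not draw a solvable layout for {face_id} "
                        f"after {max_retries} retries"
                    )
                continue
            faces.append(face)
            break
    return faces


# ---------------------------------------------------------------------------
# trials


def _face_center(geom: FaceGeometry) -> np.ndarray:
    ln = geom.center("left_nose")
    rn = geom.center("right_nose")
    return np.array([0.5 * (ln[0] + rn[0]), 0.5 * (ln[1] + rn[1])])


def generate_trial(
    config: GeneratorConfig,
    condition: Mapping[str, str],
    face: FaceGeometry,
    rng: np.random.Generator,
    delta_override: float | None = None,
    kappa_override: float | None = None,
) -> pd.DataFrame:
    """One trial's fixation sequence for a given condition cell.

    ``condition`` needs keys participant, trial, phase, orientation,
    start_position. Inverted trials are generated in the inverted face
    frame. ``delta_override``/``kappa_override`` replace the config's
    bias magnitudes (used by the null/effect dataset builders).
    """
    orientation = condition["orientation"]
    start = condition["start_position"]
    geom = face
    if orientation == "inverted" and face.orientation == "upright":
        axis = 0.5 * (face.image_bounds.y_min + face.image_bounds.y_max)
        geom = invert_geometry(face, axis)

    delta = config.delta if delta_override is None else delta_override
    kappa = config.kappa if kappa_override is None else kappa_override

    sp = start_positions(geom).as_dict()[start]
    center = _face_center(geom)
    toward = np.array(sp) - center
    nrm = np.linalg.norm(toward)
    toward = toward / nrm if nrm > 0 else np.zeros(2)
    opposite = np.array(_OPPOSITE_DIR[start])

    min_fix = (config.min_fixations_study if condition["phase"] == "study"
               else config.min_fixations_test)
    n_fix = min(min_fix + rng.geometric(config.extra_fix_p) - 1,
                config.max_fixations)

    labels = list(AOI_LABELS)
    weights = np.array([config.landmark_weights[lab] for lab in labels])
    landmark_xy = geom.centers(labels)

    xs, ys, durs = [], [], []
    for ordinal in range(1, n_fix + 1):
        if ordinal == 1:
            mu = center + kappa * toward
            sd = config.first_fix_sigma
        else:
            comp = rng.choice(len(labels), p=weights)
            shift = delta * opposite if ordinal <= 5 else np.zeros(2)
            mu = landmark_xy[comp] + shift
            sd = config.landmark_sigma
        x, y = rng.normal(mu, sd)
        xs.append(x)
        ys.append(y)
        mean_idx = min(ordinal, len(config.duration_means_ms)) - 1
        durs.append(max(rng.normal(config.duration_means_ms[mean_idx],
                                   config.duration_sd_ms),
                        config.min_duration_ms))

    if start == "center":
        lat = rng.normal(config.latency_center_mean_ms,
                         config.latency_center_sd_ms)
    else:
        lat = rng.normal(config.latency_mean_ms, config.latency_sd_ms)
    lat = max(lat, config.min_latency_ms)

    onsets = lat + np.concatenate(
        ([0.0], np.cumsum(np.asarray(durs[:-1]) + _SACCADE_GAP_MS))
    )
    return pd.DataFrame({
        "participant": condition["participant"],
        "trial": condition["trial"],
        "phase": condition["phase"],
        "orientation": orientation,
        "start_position": start,
        "face_id": face.face_id,
        "ordinal": np.arange(1, n_fix + 1),
        "x": xs,
        "y": ys,
        "onset_ms": onsets,
        "duration_ms": durs,
    })


# ---------------------------------------------------------------------------
# datasets


def _participant_streams(config: GeneratorConfig, extra: int = 0):
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_participants + extra)
    return [np.random.default_rng(s) for s in children]


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Full factorial experiment: phase x orientation x start for every
    participant, faces assigned round-robin."""
    streams = _participant_streams(config, extra=1)
    faces = generate_faces(config, streams[-1])
    frames = []
    for p in range(config.n_participants):
        rng = streams[p]
        pid = f"p{p:02d}"
        trial_no = 0
        face_cursor = p  # stagger face assignment across participants
        for phase in config.phases:
            per_cell = (config.trials_per_cell_study if phase == "study"
                        else config.trials_per_cell_test)
            for orientation in config.orientations:
                for start in config.starts:
                    for _ in range(per_cell):
                        trial_no += 1
                        face = faces[face_cursor % len(faces)]
                        face_cursor += 1
                        frames.append(generate_trial(
                            config,
                            {"participant": pid, "trial": trial_no,
                             "phase": phase, "orientation": orientation,
                             "start_position": start},
                            face, rng,
                        ))
    fixations = pd.concat(frames, ignore_index=True)[list(REQUIRED_COLUMNS)]
    behavior = generate_behavior(config, np.random.default_rng(
        np.random.SeedSequence((config.seed, 1))))
    return SyntheticDataset(fixations, faces, behavior, config)


def _two_condition_dataset(
    config: GeneratorConfig, delta_a: float, delta_b: float
) -> SyntheticDataset:
    """Two contrasted cells (start left vs right, upright, study) with
    per-condition opposite-side shifts; kappa forced to 0 so ordinal 1
    is condition-free."""
    streams = _participant_streams(config, extra=1)
    faces = generate_faces(config, streams[-1])
    per_cell = config.trials_per_cell_study
    frames = []
    for p in range(config.n_participants):
        rng = streams[p]
        pid = f"p{p:02d}"
        trial_no = 0
        face_cursor = p
        for start, delta in (("left", delta_a), ("right", delta_b)):
            for _ in range(per_cell):
                trial_no += 1
                face = faces[face_cursor % len(faces)]
                face_cursor += 1
                frames.append(generate_trial(
                    config,
                    {"participant": pid, "trial": trial_no, "phase": "study",
                     "orientation": "upright", "start_position": start},
                    face, rng,
                    delta_override=delta, kappa_override=0.0,
                ))
    fixations = pd.concat(frames, ignore_index=True)[list(REQUIRED_COLUMNS)]
    return SyntheticDataset(fixations, faces, None, config)


def generate_null_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Two conditions with *identical* fixation-generating distributions
    per ordinal (all condition-specific biases zeroed) — the
    exchangeable null for calibrating the permutation pipeline."""
    return _two_condition_dataset(config, 0.0, 0.0)


def generate_effect_dataset(
    config: GeneratorConfig, delta: float | None = None
) -> SyntheticDataset:
    """Null dataset plus a planted opposite-side mean shift of ``delta``
    degrees in the left-start condition's fixations 2-5 (mass moves to
    the right side of the face, the side opposite the start)."""
    if delta is None:
        delta = config.delta
    return _two_condition_dataset(config, delta, 0.0)


# ---------------------------------------------------------------------------
# behavior


def generate_behavior(
    config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Old/new responses from an equal-variance signal-detection model.

    Old faces carry signal mean d', new faces 0 (unit variances); the
    criterion sits midway, so P(hit) = Phi(d'/2) and P(false alarm) =
    Phi(-d'/2). One row per test trial: participant, orientation,
    is_old, response_old, rt_ms.
    """
    n_test = (config.trials_per_cell_test * len(config.starts)
              * len(config.orientations))
    rows = []
    for p in range(config.n_participants):
        pid = f"p{p:02d}"
        for orientation in config.orientations:
            d = (config.dprime_true if orientation == "upright"
                 else config.dprime_true_inverted)
            n = n_test // len(config.orientations)
            is_old = np.arange(n) < n // 2
            evidence = rng.normal(np.where(is_old, d, 0.0), 1.0)
            response_old = evidence > d / 2.0
            rt = config.rt_median_ms * np.exp(
                rng.normal(0.0, config.rt_log_sd, size=n))
            for i in range(n):
                rows.append((pid, orientation, bool(is_old[i]),
                             bool(response_old[i]), float(rt[i])))
    return pd.DataFrame(rows, columns=[
        "participant", "orientation", "is_old", "response_old", "rt_ms"])
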
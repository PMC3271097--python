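"""Face-anchored AOI geometry and start-position computation.

All coordinates are degrees of visual angle in an image-style frame:
origin at screen center, x increasing rightward, y increasing *downward*.
Seven rectangular areas of interest (AOIs) cover the internal facial
features: the two eyes and the bridge of the nose, the two half-noses,
and the two half-mouths.

Five pre-stimulus start positions are derived from the AOI centers:

* ``left`` / ``right`` — the unique point equidistant from the centers of
  the same-side eye, half-nose, and half-mouth AOIs (the circumcenter of
  the three anchor centers).
* ``upper`` / ``lower`` — on the perpendicular bisector of the two eye
  (respectively mouth) AOI centers, at a prescribed distance from each
  anchor; by convention the distance is the mean of the left and right
  start-position anchor distances.
* ``center`` — the midpoint of the two half-nose AOI centers.

Faces are aligned to a common reference frame by pure translation,
minimizing the sum of squared differences between each face's AOI
centers and the across-face average centers (closed form: the mean
offset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AOI_LABELS",
    "AoiRect",
    "Rect",
    "FaceGeometry",
    "StartPositions",
    "AlignmentTransform",
    "DegenerateGeometryError",
    "InfeasibleDistanceError",
    "circumcenter",
    "lateral_start",
    "vertical_start",
    "center_start",
    "start_positions",
    "alignment_translation",
    "reference_frame",
    "invert_geometry",
    "mirror_flip",
    "read_aoi_file",
    "write_aoi_file",
    "write_start_positions_csv",
]

#: Canonical AOI label order. ``mid_eye`` is the bridge of the nose
#: between the eyes. Also the tie-priority order for point-in-AOI
#: assignment (eyes before nose before mouth).
AOI_LABELS: tuple[str, ...] = (
    "left_eye",
    "mid_eye",
    "right_eye",
    "left_nose",
    "right_nose",
    "left_mouth",
    "right_mouth",
)

#: Label swaps under a left-right mirror flip.
_MIRROR_PAIRS = {
    "left_eye": "right_eye",
    "right_eye": "left_eye",
    "left_nose": "right_nose",
    "right_nose": "left_nose",
    "left_mouth": "right_mouth",
    "right_mouth": "left_mouth",
    "mid_eye": "mid_eye",
}

#: Triangle area (deg^2) below which three anchor points are treated as
#: collinear and the circumcenter is refused.
DEGENERACY_AREA_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Anchor points are (near-)collinear; no circumcenter exists."""


class InfeasibleDistanceError(ValueError):
    """Requested anchor distance smaller than half the anchor separation."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in degrees."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate rectangle: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def contains(self, x: float, y: float) -> bool:
        """Closed-rectangle membership (boundary points belong)."""
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


@dataclass(frozen=True)
class AoiRect(Rect):
    """One labelled facial AOI rectangle."""

    label: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.label not in AOI_LABELS:
            raise ValueError(f"unknown AOI label {self.label!r}")


@dataclass(frozen=True)
class FaceGeometry:
    """AOI layout for one face, plus the image bounds and orientation."""

    face_id: str
    aois: Mapping[str, AoiRect]
    image_bounds: Rect
    orientation: str = "upright"

    def __post_init__(self) -> None:
        if self.orientation not in ("upright", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        missing = set(AOI_LABELS) - set(self.aois)
        extra = set(self.aois) - set(AOI_LABELS)
        if missing or extra:
            raise ValueError(
                f"face {self.face_id}: AOI labels must be exactly {AOI_LABELS}; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        b = self.image_bounds
        for label, rect in self.aois.items():
            if not (
                b.x_min <= rect.x_min
                and rect.x_max <= b.x_max
                and b.y_min <= rect.y_min
                and rect.y_max <= b.y_max
            ):
                raise ValueError(
                    f"face {self.face_id}: AOI {label} outside image bounds"
                )

    def center(self, label: str) -> tuple[float, float]:
        return self.aois[label].center

    def centers(self, labels: Sequence[str] = AOI_LABELS) -> np.ndarray:
        """(n, 2) array of AOI centers in the given label order."""
        return np.array([self.aois[lab].center for lab in labels])


@dataclass(frozen=True)
class StartPositions:
    """The five pre-stimulus fixation positions for one face (degrees)."""

    left: tuple[float, float]
    right: tuple[float, float]
    upper: tuple[float, float]
    lower: tuple[float, float]
    center: tuple[float, float]

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            "left": self.left,
            "right": self.right,
            "upper": self.upper,
            "lower": self.lower,
            "center": self.center,
        }


@dataclass(frozen=True)
class AlignmentTransform:
    """Pure translation (dx, dy) into the common reference frame."""

    dx: float
    dy: float

    def apply(self, x, y):
        return np.asarray(x) + self.dx, np.asarray(y) + self.dy

    def inverse(self) -> "AlignmentTransform":
        return AlignmentTransform(-self.dx, -self.dy)


# ---------------------------------------------------------------------------
# start-position geometry


def circumcenter(
    p1: Sequence[float], p2: Sequence[float], p3: Sequence[float], *,
    face_id: str | None = None,
) -> tuple[float, float]:
    """Point equidistant from three non-collinear points.

    Closed-form intersection of two perpendicular bisectors. Raises
    :class:`DegenerateGeometryError` when the triangle area falls below
    :data:`DEGENERACY_AREA_TOL`.
    """
    ax, ay = float(p1[0]), float(p1[1])
    bx, by = float(p2[0]), float(p2[1])
    cx, cy = float(p3[0]), float(p3[1])
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    area = abs(d) / 4.0
    if area < DEGENERACY_AREA_TOL:
        who = f" for face {face_id!r}" if face_id else ""
        raise DegenerateGeometryError(
            f"anchor centers are collinear{who}: {p1}, {p2}, {p3}"
        )
    a2, b2, c2 = ax * ax + ay * ay, bx * bx + by * by, cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    return (ux, uy)


_LATERAL_ANCHORS = {
    "left": ("left_eye", "left_nose", "left_mouth"),
    "right": ("right_eye", "right_nose", "right_mouth"),
}


def lateral_start(geometry: FaceGeometry, side: str) -> tuple[float, float]:
    """Left or right start position: circumcenter of the same-side
    eye, half-nose, and half-mouth AOI centers."""
    try:
        labels = _LATERAL_ANCHORS[side]
    except KeyError:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}") from None
    pts = [geometry.center(lab) for lab in labels]
    return circumcenter(*pts, face_id=geometry.face_id)


def vertical_start(
    geometry: FaceGeometry, which: str, target_distance: float
) -> tuple[float, float]:
    """Upper or lower start position.

    The point lies on the perpendicular bisector of the two anchor
    centers (the eyes for ``upper``, the half-mouths for ``lower``) at
    ``target_distance`` from each. Of the two candidate solutions the
    one away from the other feature row is returned — the forehead side
    of the eyes for ``upper``, the chin side of the mouth for ``lower``
    — judged in the face's own frame, so the rule is orientation-proof.
    """
    if which == "upper":
        a = np.array(geometry.center("left_eye"))
        b = np.array(geometry.center("right_eye"))
        away_from = 0.5 * (
            np.array(geometry.center("left_mouth"))
            + np.array(geometry.center("right_mouth"))
        )
    elif which == "lower":
        a = np.array(geometry.center("left_mouth"))
        b = np.array(geometry.center("right_mouth"))
        away_from = 0.5 * (
            np.array(geometry.center("left_eye"))
            + np.array(geometry.center("right_eye"))
        )
    else:
        raise ValueError(f"which must be 'upper' or 'lower', got {which!r}")

    mid = 0.5 * (a + b)
    half_sep = 0.5 * float(np.linalg.norm(b - a))
    if target_distance <= half_sep:
        raise InfeasibleDistanceError(
            f"face {geometry.face_id}: target distance {target_distance:.4f} deg "
            f"<= half anchor separation {half_sep:.4f} deg"
        )
    h = math.sqrt(target_distance**2 - half_sep**2)
    if half_sep > 0:
        u = (b - a) / (2.0 * half_sep)
        normal = np.array([-u[1], u[0]])
    else:  # coincident anchors: bisector direction is arbitrary, use +y
        normal = np.array([0.0, 1.0])
    c1, c2 = mid + h * normal, mid - h * normal
    # pick the candidate farther from the opposing feature row
    if np.linalg.norm(c1 - away_from) >= np.linalg.norm(c2 - away_from):
        chosen = c1
    else:
        chosen = c2
    return (float(chosen[0]), float(chosen[1]))


def center_start(geometry: FaceGeometry) -> tuple[float, float]:
    """Center start position: midpoint of the two half-nose AOI centers."""
    ln = geometry.center("left_nose")
    rn = geometry.center("right_nose")
    return (0.5 * (ln[0] + rn[0]), 0.5 * (ln[1] + rn[1]))


def start_positions(geometry: FaceGeometry) -> StartPositions:
    """All five start positions for one face.

    The upper/lower anchor distance is constrained to the mean of the
    left and right start positions' distances to their own anchors.
    """
    left = lateral_start(geometry, "left")
    right = lateral_start(geometry, "right")
    d_left = math.dist(left, geometry.center("left_eye"))
    d_right = math.dist(right, geometry.center("right_eye"))
    d_vert = 0.5 * (d_left + d_right)
    upper = vertical_start(geometry, "upper", d_vert)
    lower = vertical_start(geometry, "lower", d_vert)
    return StartPositions(
        left=left, right=right, upper=upper, lower=lower,
        center=center_start(geometry),
    )


# ---------------------------------------------------------------------------
# alignment


def alignment_translation(
    face_centers: np.ndarray, reference_centers: np.ndarray
) -> AlignmentTransform:
    """Translation minimizing the SSD between a face's AOI centers and
    the reference centers.

    Closed form: under translation-only the minimizer is the mean of
    (reference - face) over the labelled centers.
    """
    fc = np.asarray(face_centers, dtype=float)
    rc = np.asarray(reference_centers, dtype=float)
    if fc.shape != rc.shape or fc.ndim != 2 or fc.shape[1] != 2:
        raise ValueError(
            f"center lists must be matching (n, 2) arrays, got {fc.shape} vs {rc.shape}"
        )
    dx, dy = (rc - fc).mean(axis=0)
    return AlignmentTransform(float(dx), float(dy))


def reference_frame(faces: Iterable[FaceGeometry]) -> np.ndarray:
    """Per-label mean of AOI centers across faces, in AOI_LABELS order."""
    stacks = [face.centers() for face in faces]
    if not stacks:
        raise ValueError("need at least one face")
    return np.mean(stacks, axis=0)


def face_alignment(
    face: FaceGeometry, reference: np.ndarray
) -> AlignmentTransform:
    """Alignment of one face to the reference-frame centers."""
    return alignment_translation(face.centers(), reference)


# ---------------------------------------------------------------------------
# flips


def invert_geometry(geometry: FaceGeometry, axis_y: float) -> FaceGeometry:
    """Reflect the face about the horizontal line y = axis_y.

    Every y becomes 2*axis_y - y (bounds re-sorted); AOI labels keep
    their identities (the left eye stays the left eye) and the
    orientation flag flips.
    """
    def flip_rect(r: Rect) -> tuple[float, float, float, float]:
        y0, y1 = 2 * axis_y - r.y_max, 2 * axis_y - r.y_min
        return (r.x_min, y0, r.x_max, y1)

    aois = {
        lab: AoiRect(*flip_rect(r), label=lab) for lab, r in geometry.aois.items()
    }
    bounds = Rect(*flip_rect(geometry.image_bounds))
    flipped = "inverted" if geometry.orientation == "upright" else "upright"
    return FaceGeometry(geometry.face_id, aois, bounds, flipped)


def mirror_flip(geometry: FaceGeometry, axis_x: float) -> FaceGeometry:
    """Reflect the face about the vertical line x = axis_x, swapping
    left/right AOI labels (the mirror image of the left eye is a right
    eye)."""
    def flip_rect(r: Rect) -> tuple[float, float, float, float]:
        x0, x1 = 2 * axis_x - r.x_max, 2 * axis_x - r.x_min
        return (x0, r.y_min, x1, r.y_max)

    aois = {}
    for lab, r in geometry.aois.items():
        new_lab = _MIRROR_PAIRS[lab]
        aois[new_lab] = AoiRect(*flip_rect(r), label=new_lab)
    bounds = Rect(*flip_rect(geometry.image_bounds))
    return FaceGeometry(geometry.face_id, aois, bounds, geometry.orientation)


# ---------------------------------------------------------------------------
# file IO — tab-delimited AOI dialect:
#   face_id <TAB> label <TAB> x_min <TAB> y_min <TAB> x_max <TAB> y_max
# plus one row per face with label "image" carrying the image bounds.

_AOI_COLUMNS = ["face_id", "label", "x_min", "y_min", "x_max", "y_max"]


def write_aoi_file(faces: Iterable[FaceGeometry], path: str | Path) -> None:
    rows = []
    for face in faces:
        b = face.image_bounds
        rows.append((face.face_id, "image", b.x_min, b.y_min, b.x_max, b.y_max))
        for lab in AOI_LABELS:
            r = face.aois[lab]
            rows.append((face.face_id, lab, r.x_min, r.y_min, r.x_max, r.y_max))
    pd.DataFrame(rows, columns=_AOI_COLUMNS).to_csv(path, sep="\t", index=False)


def read_aoi_file(
    path: str | Path, orientation: str = "upright"
) -> list[FaceGeometry]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_AOI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"AOI file {path}: missing columns {sorted(missing)}")
    faces = []
    for face_id, grp in df.groupby("face_id", sort=False):
        by_label = {row.label: row for row in grp.itertuples()}
        if "image" not in by_label:
            raise ValueError(f"AOI file {path}: face {face_id} lacks an image row")
        img = by_label.pop("image")
        bounds = Rect(img.x_min, img.y_min, img.x_max, img.y_max)
        aois = {
            lab: AoiRect(r.x_min, r.y_min, r.x_max, r.y_max, label=lab)
            for lab, r in by_label.items()
        }
        faces.append(FaceGeometry(str(face_id), aois, bounds, orientation))
    return faces


def write_start_positions_csv(
    faces: Iterable[FaceGeometry], path: str | Path
) -> pd.DataFrame:
    """Compute and export start positions as CSV
    (face_id, position_name, x, y). Returns the table."""
    rows = []
    for face in faces:
        sp = start_positions(face)
        for name, (x, y) in sp.as_dict().items():
            rows.append((face.face_id, name, x, y))
    table = pd.DataFrame(rows, columns=["face_id", "position_name", "x", "y"])
    table.to_csv(path, index=False)
    return table
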
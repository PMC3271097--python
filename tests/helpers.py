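"""Shared test helpers."""

import numpy as np

from fixmap.geometry import AoiRect, FaceGeometry
from fixmap.synth import CANONICAL_BOUNDS, CANONICAL_LAYOUT


def random_face(rng: np.random.Generator, face_id: str = "f",
                jitter: float = 0.2) -> FaceGeometry:
    """Canonical layout with per-AOI translation jitter."""
    aois = {}
    for lab, (x0, y0, x1, y1) in CANONICAL_LAYOUT.items():
        dx, dy = rng.normal(0, jitter, 2)
        aois[lab] = AoiRect(x0 + dx, y0 + dy, x1 + dx, y1 + dy, label=lab)
    return FaceGeometry(face_id, aois, CANONICAL_BOUNDS, "upright")
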
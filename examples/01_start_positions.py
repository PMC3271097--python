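"""Compute face-anchored start positions from AOI rectangles.

Builds three synthetic face layouts (canonical 7-AOI geometry plus
per-face jitter, standing in for annotated photographs) and derives the
five pre-stimulus start positions each face defines: left/right at the
point equidistant from the same-side eye, half-nose, and half-mouth
centers; upper/lower on the eye/mouth perpendicular bisectors at the
mean lateral anchor distance; center at the half-nose midpoint.
"""

import numpy as np

from fixmap import GeneratorConfig, start_positions
from fixmap.synth import generate_faces

faces = generate_faces(GeneratorConfig(n_faces=3), np.random.default_rng(0))

for face in faces:
    sp = start_positions(face)
    print(f"\n{face.face_id} (degrees of visual angle, y increases downward):")
    for name, (x, y) in sp.as_dict().items():
        print(f"  {name:>6}: ({x:+6.2f}, {y:+6.2f})")

print(
    "\nLateral starts sit ~3 deg outside the cheeks, upper/lower above the "
    "eyes and below the mouth, center on the nose - the five enforced "
    "pre-stimulus gaze positions, defined relative to each face's own "
    "features."
)
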
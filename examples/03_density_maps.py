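"""Build aligned spatial fixation-density maps and profile plots.

Each fixation contributes an isotropic Gaussian (sd 0.3 deg) on a
common reference frame reached by translation-only alignment of each
face's AOI centers to the across-face average. The map's integral
equals the fixation count; marginal profiles summarize the density
along each axis.
"""

import numpy as np

from fixmap import GeneratorConfig, GridSpec, density_map, profile_plots
from fixmap.density import align_fixations
from fixmap.geometry import reference_frame
from fixmap.preprocessing import clamp_to_image, select_first_k
from fixmap.synth import generate_dataset

cfg = GeneratorConfig(n_participants=5, n_faces=10, trials_per_cell_study=3,
                      trials_per_cell_test=1, seed=21)
ds = generate_dataset(cfg)

fix = clamp_to_image(ds.fixations, ds.faces[0].image_bounds)
fix = select_first_k(fix, k=5)
fix = fix[(fix["phase"] == "study") & (fix["orientation"] == "upright")]
fix = align_fixations(fix, ds.geometries, reference_frame(ds.faces))

grid = GridSpec.from_bounds(ds.faces[0].image_bounds, cell=0.05, pad=1.0)
m = density_map(fix, grid, sigma=0.3)

print(f"grid: {grid.n_x} x {grid.n_y} pixels at {grid.cell} deg/px")
print(f"fixations rasterized: {m.n_fixations}")
print(f"map mass (integral):  {m.mass:.2f}  <- equals the fixation count")
print(f"peak density:         {m.values.max():.2f} per deg^2")

px, py = profile_plots(m)
peak_x = grid.x_centers[px.argmax()]
peak_y = grid.y_centers[py.argmax()]
print(f"density peak at x = {peak_x:+.2f}, y = {peak_y:+.2f} deg")
print("The peak sits in the eye region (negative y = upper face), the "
      "classic face-viewing pattern the generator emulates.")
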
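"""Cluster-corrected permutation contrast of two start positions.

Plants a 1.5-deg opposite-side shift in the left-start condition's
fixations 2-5, then runs the full inference chain: stratified
permutations (fixation locations exchanged only within participant x
ordinal), per-iteration group difference maps, sign-adaptive pixel
p-values thresholded at p < 0.01, and max-cluster-size correction at a
0.05 cluster threshold. Iterations are reduced from the full 10,400 /
2,600 defaults to keep the example quick.
"""

from fixmap import GeneratorConfig, PermutationSpec, run_contrast
from fixmap.calibration import CalibrationSpec, prepare_contrast_data
from fixmap.synth import generate_effect_dataset

cfg = GeneratorConfig(n_participants=20, trials_per_cell_study=8,
                      n_faces=16, seed=7)
ds = generate_effect_dataset(cfg, delta=1.5)

fix, grid, bounds = prepare_contrast_data(ds, CalibrationSpec())
spec = PermutationSpec(n_iterations=500, n_cluster_maps=125)
result = run_contrast(fix, "left", "right", grid, spec, seed=7)

print(f"participants: {result.n_participants}, grid {grid.n_x}x{grid.n_y} px")
print(f"uncorrected significant pixels: {(result.mask != 0).sum()}")
print(f"null max-cluster-size 95th pct region: "
      f"smallest surviving size = {result.cluster_size_threshold:g} px")
print("\nclusters (sign +1 = left-start > right-start density):")
cols = ["id", "sign", "size", "p_corrected", "survives"]
print(result.clusters[cols].to_string(index=False))
surv = result.clusters[result.clusters["survives"]]
print(f"\n{len(surv)} cluster(s) survive correction; the positive surviving "
      "cluster lies on the right half of the face - the side opposite the "
      "left start position, i.e. the planted effect is recovered with "
      "family-wise error control.")
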
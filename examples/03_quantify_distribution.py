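"""Quantify puncta and their spatial distribution along the neurite.

Uses ground-truth segmentations from the generator (so the example runs in
seconds), maps each punctum to its nearest skeleton node, and prints the
per-image summary plus a pooled probability-density histogram.
"""

import dataclasses

import numpy as np

import punctaseg as ps
from punctaseg.quantify import extract_puncta, map_puncta_to_skeleton, population_density

spec = ps.preset_spec("small_high_snr", seed=21, n_clutter=0)
worms = []
for i in range(5):
    s = ps.generate_sample(dataclasses.replace(spec, seed=21 + i), image_id=f"worm{i}")
    puncta = extract_puncta(s.synapse_truth, s.image, connectivity=26)
    worms.append(map_puncta_to_skeleton(puncta, s.skeleton_truth))

summary = worms[0].summarize()
print(f"worm 0: {summary.puncta_count} puncta, total volume {summary.total_volume:.0f} um^3")
print(f"        synapse domain {summary.domain_length:.1f} um, "
      f"count density {summary.count_density:.3f} per um")

profile = population_density(worms, n_bins=10)
print(f"\npooled density over {profile.n_worms} worms "
      f"(integral = {profile.integral():.6f}):")
for left, right, d in zip(profile.bin_edges[:-1], profile.bin_edges[1:], profile.density):
    bar = "#" * int(round(d * 20))
    print(f"  [{left:.1f}, {right:.1f})  {d:5.2f}  {bar}")
print(
    "\nPositions run from 0 (soma) to 1 (furthest terminal); density is a\n"
    "probability density (flat = 1 everywhere), voxel-weighted and pooled\n"
    "across the population. Puncta are placed uniformly here, so the\n"
    f"profile is flat up to sampling noise (max |dev| "
    f"{np.abs(profile.density - 1).max():.2f})."
)
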
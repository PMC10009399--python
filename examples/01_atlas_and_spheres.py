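"""Load the bundled seed atlas and inspect its sphere masks and pair blocks.

The atlas is an ordered table of 5-mm spherical seeds over three networks
(CON, DMN, OST).  On a 2-mm grid a 5-mm sphere centered on a voxel covers
exactly 81 voxel centers.
"""

import numpy as np

from roiconn import GridSpec, block_index, bundled_atlas, sphere_mask

atlas = bundled_atlas()
print(f"atlas: {len(atlas)} ROIs")
for net, idx in atlas.networks.items():
    print(f"  {net}: {len(idx)} ROIs -> {[atlas.rois[i].label for i in idx]}")

# a 2-mm grid around the first ROI, with a voxel center exactly on it
roi = atlas.rois[0]
grid = GridSpec.isotropic((40, 40, 40), 2.0, roi.center_mni - 40.0)
vox = sphere_mask(roi, grid)
print(f"\n{roi.label} sphere on a 2-mm grid: {len(vox)} voxels "
      "(the 5-mm sphere covers 81 centers when centered on a voxel)")

pairs = block_index(atlas)
print("\npair blocks (the six metrics average z over these ROI pairs):")
for net, ps in pairs.within.items():
    print(f"  within_{net}: {len(ps)} pairs")
for (a, b), ps in pairs.between.items():
    print(f"  between_{a}_{b}: {len(ps)} pairs")
total = sum(len(p) for p in pairs.within.values()) + \
    sum(len(p) for p in pairs.between.values())
print(f"  total {total} = {len(atlas)}*{len(atlas) - 1}/2 off-diagonal pairs")
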
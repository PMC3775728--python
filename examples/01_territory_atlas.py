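"""Build the parametric coronal territory atlas and measure its regions.

The atlas defines, on a 128x128 grid at the native CT in-plane scale
(50 mm / 512), the two hemispheres, cortex vs. subcortex, the lateral MCA
territory and the small medial subcortical AChA territory (caudal slice
only, -2.4 mm bregma).
"""

from achastroke import build_atlas, mask_volume, save_atlas

atlas = build_atlas()
grid = atlas.grid

print(f"grid: {grid.n_rows}x{grid.n_cols}, pixel {grid.pixel_size:.4f} mm, "
      f"slices at {grid.bregma_levels} mm bregma")
for name, mask in atlas.masks.items():
    counts = [int(c) for c in mask.sum(axis=(1, 2))]
    vol = mask_volume(mask, grid)
    print(f"{name:18s} voxels/slice {list(counts)}  volume {vol:8.2f} mm^3")

save_atlas(atlas, "atlas.tif")
print("\nSaved atlas.tif (+ atlas.json sidecar).")
print("The AChA territory exists only on the caudal slice and lies entirely")
print("within the subcortex; left/right masks are exact mirror images.")
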
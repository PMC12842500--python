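"""Render a synthetic CT with one 10 mm stone and measure it.

A spherical 400 HU stone is digitized at 1 mm voxels inside an ellipsoidal
kidney; threshold segmentation at 130 HU recovers the digitized voxel set
exactly, so the segmented volume differs from the analytic sphere volume
only by the digitization itself.
"""

from stoneburden.phantom import Ellipsoid, PhantomSpec, StoneSpec, generate_phantom
from stoneburden.volumetry import build_inventory

spec = PhantomSpec(
    grid_shape=(43, 43, 43),
    voxel_spacing=(1.0, 1.0, 1.0),
    kidneys={"right": Ellipsoid(center=(20.3, 20.5, 20.6), semi_axes=(18, 18, 18))},
    stones=[StoneSpec.sphere("right", (20.3, 20.5, 20.6), radius=10.0)],
    noise_sd=0.0,
)
image, mask, truth = generate_phantom(spec)
inventory = build_inventory(image, mask, threshold=130)

stone = inventory.stones[0]
print(f"analytic volume : {truth[0].analytic_volume_ml:.5f} mL")
print(f"digitized volume: {truth[0].digitized_volume_ml:.5f} mL")
print(f"segmented volume: {stone.volume_ml:.5f} mL "
      f"({stone.voxel_count} voxels)")
print(f"max diameter    : {stone.max_diam_xz_mm:.2f} mm (x-z), "
      f"{stone.max_diam_yz_mm:.2f} mm (y-z)")
print(f"HU (min/mean/max): {stone.min_hu:.0f}/{stone.mean_hu:.0f}/{stone.max_hu:.0f}")
# The segmented and digitized volumes agree exactly (zero voxel error); both
# sit within ~0.1% of the analytic 4.18879 mL at this fine, isotropic spacing.
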
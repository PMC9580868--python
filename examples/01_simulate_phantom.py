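"""Generate the two phantom families and inspect their geometry.

Blobs emulate bulky tumour-like masses, tubes emulate thin neurite-like
networks; both come with a binary ground truth for scoring.
"""

import numpy as np

from voxelearn import PhantomSpec, generate_phantom

blob_spec = PhantomSpec(kind="blob", dims=(32, 32, 32), noise_sigma=38.0, seed=12)
blob_vol, blob_gt = generate_phantom(blob_spec)

tube_spec = PhantomSpec(
    kind="tubes", dims=(48, 48, 48), noise_sigma=38.0,
    geometry={"n_tubes": 3, "tube_radius": 1.5}, seed=13,
)
tube_vol, tube_gt = generate_phantom(tube_spec)

for name, vol, gt in [("blob", blob_vol, blob_gt), ("tubes", tube_vol, tube_gt)]:
    lo, hi = vol.intensity_range()
    print(f"{name}: dims={vol.dims}  object voxels={int(gt.sum())} "
          f"({100 * gt.mean():.2f}% of volume)  intensity [{lo:.0f}, {hi:.0f}]")

# The object fraction shows the structural contrast the classifiers face:
# the blob is a compact region, the tubes occupy a sparse thin network.
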
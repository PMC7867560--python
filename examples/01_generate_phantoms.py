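"""Generate a small labelled phantom cohort and inspect its manifest.

Each stack is a 5x5x5 cm NECT cube with one calcification near the centre:
stones tend to carry a soft-tissue rim, phleboliths a central lucency
and/or a comet tail.  Both classes share their size and attenuation
distributions, so those two measurements alone cannot separate them.
"""

import numpy as np

from calcnet import PhantomParams, generate_cohort, generate_stack

stacks, manifest = generate_cohort(n_stones=4, n_phleboliths=4, seed=11)
print(manifest.to_string(index=False))

# one custom stone, bit-reproducible from its seed
params = PhantomParams("stone", max_diameter_mm=6.0, peak_hu=800.0,
                       rim_present=True, seed=3)
stack = generate_stack(params, id="demo")
calcified = stack.values >= 250.0
print(f"\ncustom stone: {calcified.sum()} voxels >= 250 HU, "
      f"peak {stack.values.max():.0f} HU, "
      f"background median {np.median(stack.values):.0f} HU")
# the voxel counts and HU summaries above are what the segmentation and
# comparator stages will consume downstream
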
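"""Compute the boundary-aware training weight map for a two-lesion mask.

The weight at each pixel is the class-balance term plus an exponential
bonus that grows as the summed distances to the two nearest lesion
objects shrink, so the strip between nearby lesions gets the highest
training pressure.
"""

import numpy as np

import dermcad as dc

mask = np.zeros((64, 64), dtype=np.uint8)
yy, xx = np.mgrid[0:64, 0:64]
mask[np.hypot(yy - 32, xx - 20) <= 8] = 1   # left lesion
mask[np.hypot(yy - 32, xx - 44) <= 8] = 1   # right lesion

fields = dc.object_distance_fields(mask)
wm = dc.weight_map(mask, omega0=10.0, sigma=5.0)

mid = (32, 32)  # pixel in the gap between the lesions
far = (2, 2)    # background corner
print(f"components found: {fields.n_objects}")
print(f"gap pixel    d1={fields.d1[mid]:.1f} d2={fields.d2[mid]:.1f} "
      f"weight={wm.weights[mid]:.3f}")
print(f"corner pixel d1={fields.d1[far]:.1f} d2={fields.d2[far]:.1f} "
      f"weight={wm.weights[far]:.3f}")
print("-> the inter-lesion gap is weighted far above plain class balance,")
print("   forcing the segmenter to learn the separating border.")
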
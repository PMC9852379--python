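"""Symmetric brain phantoms, lesions and erase masks.

Builds a mirror-symmetric 2-D brain phantom with a planted label map,
adds a unilateral lesion, and draws a random erase mask of controlled
coverage — the synthetic inputs every other stage consumes.
"""

import numpy as np

from hydroparc.synthetic_data import (
    Lesion,
    PhantomSpec,
    make_erase_mask,
    make_symmetric_phantom,
)

# a lesion-free phantom is exactly equal to its left-right mirror
img, labels = make_symmetric_phantom(
    PhantomSpec(image_size=64, n_regions=12, seed=0)
)
print(f"phantom: {img.shape}, {labels.max()} regions,"
      f" mirror-symmetric: {np.array_equal(img, img[:, ::-1])}")

# a unilateral lesion breaks the symmetry only locally
lesioned, _ = make_symmetric_phantom(
    PhantomSpec(
        image_size=64, n_regions=12, seed=0,
        lesion=Lesion(center=(32, 16), radii=(8, 7), intensity_shift=-0.4),
    )
)
asym = np.abs(lesioned - lesioned[:, ::-1]) > 1e-9
print(f"lesioned phantom: asymmetric pixels = {asym.sum()}"
      f" (confined to the lesion and its mirror)")

# erase masks mark the abnormal region removed before inpainting
mask = make_erase_mask(64, n_shapes=2, coverage_range=(0.05, 0.2),
                       seed=1, side="left")
print(f"erase mask: coverage {mask.mean():.3f}"
      f" (target band 0.05-0.20), left hemisphere only:"
      f" {mask[:, 32:].sum() == 0}")
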
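"""Inpainting-mediated atlas parcellation versus direct registration.

Builds hydrocephalus-like subjects (atlas anatomy under a smooth warp
plus a large unilateral CSF-dark cavity), then transfers the atlas labels
two ways: through the inpainted pseudo-normal image, and by registering
the atlas directly onto the abnormal image.  Label Dice against the
planted ground truth quantifies the benefit.  About two minutes on CPU.
"""

import warnings

import numpy as np

from hydroparc.experiments import parcellation_benefit, train_phantom_inpainter

warnings.filterwarnings("ignore")

model = train_phantom_inpainter()  # small flip-guided model, ~1 min
res = parcellation_benefit(model=model, n_phantoms=10, seed=0)

print("mean label Dice per phantom")
print("  with inpainting mediation:", np.round(res.dice_with, 3))
print("  direct registration:      ", np.round(res.dice_without, 3))
print(f"inpainting route wins on {res.n_wins}/10 phantoms"
      f" (mean {np.mean(res.dice_with):.3f} vs"
      f" {np.mean(res.dice_without):.3f})")
print("(the mediated route registers the atlas to a pseudo-normal image"
      " first, so the cavity cannot corrupt the alignment)")
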
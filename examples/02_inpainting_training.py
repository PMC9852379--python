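"""Train the symmetry-guided inpainting GAN on phantoms.

Trains a small flip-guided partial-convolution generator for a few
epochs, inpaints a held-out phantom, and reports PSNR/SSIM against the
intact ground truth.  Runs in about a minute on one CPU.
"""

import warnings

import numpy as np

from hydroparc import inpainting as ip
from hydroparc.synthetic_data import (
    PhantomSpec,
    make_erase_mask,
    make_symmetric_phantom,
)

warnings.filterwarnings("ignore")

train_imgs, train_masks = [], []
for i in range(40):
    img, _ = make_symmetric_phantom(PhantomSpec(image_size=48, seed=i))
    train_imgs.append(img)
    train_masks.append(
        make_erase_mask(48, 2, (0.05, 0.2), seed=i, side="left")
    )

model, log = ip.train(
    ip.make_erased_pair(np.stack(train_imgs), np.stack(train_masks)),
    ip.GeneratorConfig(),          # flip channel + flip-consistency loss on
    epochs=8,
    seed=0,
    batch_size=20,
)
print("per-epoch generator loss:",
      [round(v, 2) for v in log["g_total"]])

# held-out phantom: the intact right hemisphere guides the left-side fill
test_img, _ = make_symmetric_phantom(PhantomSpec(image_size=48, seed=10_000))
test_mask = make_erase_mask(48, 2, (0.05, 0.2), seed=10_000, side="left")
filled = model.inpaint(test_img, test_mask)
scores = ip.evaluate(filled, test_img)
print(f"held-out fill quality: PSNR {scores['psnr']:.2f} dB,"
      f" SSIM {scores['ssim']:.3f}, L1 {scores['l1']:.4f}")
print("(higher PSNR/SSIM = closer to the true intact image;"
      " a zero-fill baseline sits far below)")
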
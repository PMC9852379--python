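"""Symmetry-guided partial-convolution GAN for brain abnormality inpainting.

Healthy brain anatomy is approximately left-right mirror symmetric, while
hydrocephalic lesions and deformations are typically unilateral.  The
generator therefore receives, besides the erased image and its validity
mask, the mirrored copy of both: the intact contralateral hemisphere is
available in the input exactly where tissue is missing.  Training combines

* masked L1 terms over valid and erased pixels (weights 1 and 6),
* a perceptual L1 and two Gram-matrix style terms from a fixed
  convolutional feature extractor (weights 0.05 and 120),
* a total-variation smoothness penalty over the (dilated) hole (weight 0.1),
* a flip-consistency L1 between the outputs of the raw and mirrored passes,
* and an adversarial term -log D(fake) with weight 0.1 against an encoder
  discriminator trained with binary cross-entropy.

Every convolution in the generator is a partial convolution: the window sum
is taken over valid pixels only, renormalized by window_size / n_valid, and
the validity mask is updated (a location becomes valid once any input in
its window was valid), so stacked layers progressively fill the hole.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

from . import nn
from .nn import Tensor, Parameter

__all__ = [
    "ErasedPair",
    "LossWeights",
    "GeneratorConfig",
    "InpaintResult",
    "InpaintingModel",
    "make_erased_pair",
    "partial_conv",
    "generator_forward",
    "inpainting_loss",
    "perceptual_loss",
    "style_loss",
    "tv_loss",
    "flip_loss",
    "total_generator_loss",
    "discriminator_loss",
    "train",
    "evaluate",
    "save_model",
    "load_model",
]

_EPS = 1e-7  # probability clamp: the BCE losses are undefined at exactly 0/1


# ---------------------------------------------------------------------------
# data containers

@dataclass
class ErasedPair:
    """Ground truth, validity mask (1 = valid, 0 = erased), the erased
    image and the mirrored copies that form the network input."""

    I_gt: np.ndarray       # (N, 1, H, W) float32 in [0, 1]
    M: np.ndarray          # (N, 1, H, W) float32 binary
    I_erased: np.ndarray
    I_erased_flip: np.ndarray
    M_flip: np.ndarray

    @property
    def I_gt_flip(self) -> np.ndarray:
        return self.I_gt[..., ::-1].copy()


def _to_nchw(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img, dtype=np.float32)
    if a.ndim == 2:
        a = a[None, None]
    elif a.ndim == 3:
        a = a[:, None]
    return a


def make_erased_pair(image: np.ndarray, erase_mask: np.ndarray) -> ErasedPair:
    """Build an :class:`ErasedPair` from image(s) and erase-region mask(s)
    (erase mask: 1 = erased).  Erased input pixels are set to exactly 0."""
    I_gt = _to_nchw(image)
    erase = _to_nchw(erase_mask)
    if I_gt.shape != erase.shape:
        raise ValueError(f"image {I_gt.shape} and mask {erase.shape} differ")
    M = (erase == 0).astype(np.float32)
    I_erased = I_gt * M
    return ErasedPair(
        I_gt=I_gt,
        M=M,
        I_erased=I_erased,
        I_erased_flip=I_erased[..., ::-1].copy(),
        M_flip=M[..., ::-1].copy(),
    )


@dataclass(frozen=True)
class LossWeights:
    """Loss-term weights; defaults are the published training constants."""

    w_valid: float = 1.0
    w_erase: float = 6.0
    w_perceptual: float = 0.05
    w_style: float = 120.0
    w_tv: float = 0.1
    w_adv: float = 0.1

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    depth: int = 2               # number of stride-2 encoder levels
    base_channels: int = 8
    kernel_size: int = 3
    use_flip: bool = True        # mirrored input channel + flip loss
    extractor: str = "fixed-random"  # "fixed-random" | "none"
    tv_whole_image: bool = False

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")


@dataclass
class InpaintResult:
    I_out: Tensor        # raw-pass output, raw orientation
    I_outflip: Tensor    # flipped-pass output re-flipped to raw orientation
    I_comp: Tensor       # M*I_gt + (1-M)*I_out
    I_comp_flip: Tensor  # composite of the re-flipped flipped-pass output
    final_mask: np.ndarray


# ---------------------------------------------------------------------------
# partial convolution

def _mask_window_sum(mask: np.ndarray, k: int, stride: int) -> np.ndarray:
    cols, (ho, wo) = nn._im2col(mask, k, stride)
    return cols.sum(axis=1).reshape(mask.shape[0], 1, ho, wo)


def partial_conv(
    image: np.ndarray | Tensor,
    mask: np.ndarray,
    weight: np.ndarray | Tensor,
    bias: np.ndarray | Tensor | None = None,
    stride: int = 1,
):
    """One partial-convolution layer.

    At each output location with n valid mask pixels in its k x k window the
    output is ``W^T (X*M) * (k*k / n) + b``; where the window holds no valid
    pixel the output is 0 and the updated mask is 0, else 1.

    Accepts plain arrays (returns arrays) or autodiff Tensors (returns a
    Tensor plus the new mask array).
    """
    as_array = not isinstance(image, Tensor)
    orig_ndim = None
    if as_array:
        arr = np.asarray(image, dtype=np.float32)
        orig_ndim = arr.ndim
        x = Tensor(_to_nchw(arr))
    else:
        x = image
    m = _to_nchw(mask)
    if x.data.shape[-2:] != m.shape[-2:]:
        raise ValueError(
            f"image {x.data.shape} and mask {m.shape} grids differ"
        )
    w = weight if isinstance(weight, Tensor) else Tensor(np.asarray(weight, np.float32))
    k = w.data.shape[-1]
    b = bias if bias is None or isinstance(bias, Tensor) else Tensor(
        np.asarray(bias, np.float32)
    )
    msum = _mask_window_sum(m, k, stride)
    valid = (msum > 0).astype(np.float32)
    ratio = np.where(msum > 0, (k * k) / np.maximum(msum, 1e-8), 0.0).astype(
        np.float32
    )
    y = nn.conv2d(x * Tensor(m), w, None, stride=stride)
    y = y * Tensor(ratio)
    if b is not None:
        y = y + b.reshape(1, -1, 1, 1)
    y = y * Tensor(valid)
    if as_array:
        out, vm = y.data, valid
        if orig_ndim == 2:
            return out[0, 0] if out.shape[1] == 1 else out[0], vm[0, 0]
        return out, vm
    return y, valid


class _PConvLayer:
    def __init__(self, cin, cout, k, stride, rng, scale=None):
        fan_in = cin * k * k
        s = scale if scale is not None else np.sqrt(2.0 / fan_in)
        self.W = Parameter(rng.normal(0.0, s, size=(cout, cin, k, k)))
        self.b = Parameter(np.zeros(cout))
        self.stride = stride

    def __call__(self, x, mask):
        return partial_conv(x, mask, self.W, self.b, stride=self.stride)

    @property
    def params(self):
        return [self.W, self.b]


class FixedConvExtractor:
    """Fixed random-weight convolutional feature map for the perceptual and
    style terms.  Its weights are never trained; gradients flow only to the
    input image.  A fixed random deep feature is a valid perceptual metric
    when no pretrained network is available."""

    def __init__(self, seed: int = 1234, channels=(8, 16)):
        rng = np.random.default_rng(seed)
        self.layers = []
        cin = 1
        for cout in channels:
            W = Tensor(
                rng.normal(0.0, np.sqrt(2.0 / (cin * 9)), size=(cout, cin, 3, 3)).astype(
                    np.float32
                )
            )
            self.layers.append(W)
            cin = cout

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for W in self.layers:
            h = nn.conv2d(h, W, None, stride=2).leaky_relu(0.2)
        return h


class Generator:
    """Partial-convolution U-Net.  With ``use_flip`` the erased image and
    its mirror each pass through a stem partial convolution and are
    concatenated; without it a single stem of the same total width is used."""

    def __init__(self, config: GeneratorConfig, rng):
        C, k = config.base_channels, config.kernel_size
        self.config = config
        if config.use_flip:
            half = max(C // 2, 1)
            self.stem_raw = _PConvLayer(1, half, k, 1, rng)
            self.stem_mir = _PConvLayer(1, C - half, k, 1, rng)
            self.stems = [self.stem_raw, self.stem_mir]
        else:
            self.stem = _PConvLayer(1, C, k, 1, rng)
            self.stems = [self.stem]
        self.encoders = []
        ch = C
        for _ in range(config.depth):
            self.encoders.append(_PConvLayer(ch, ch * 2, k, 2, rng))
            ch *= 2
        self.decoders = []
        for _ in range(config.depth):
            skip = ch // 2
            self.decoders.append(_PConvLayer(ch + skip, skip, k, 1, rng))
            ch //= 2
        self.out_layer = _PConvLayer(ch, 1, k, 1, rng, scale=0.05)

    @property
    def params(self):
        ps = []
        for layer in self.stems + self.encoders + self.decoders + [self.out_layer]:
            ps.extend(layer.params)
        return ps

    def forward(self, I_er, M, I_er_mir=None, M_mir=None):
        """One pass; inputs are (N,1,H,W) arrays in the pass's own frame."""
        if self.config.use_flip:
            f_a, m_a = self.stem_raw(Tensor(I_er), M)
            f_b, m_b = self.stem_mir(Tensor(I_er_mir), M_mir)
            h = nn.concat([f_a, f_b], axis=1).leaky_relu(0.2)
            mask = np.maximum(m_a, m_b)
        else:
            h, mask = self.stem(Tensor(I_er), M)
            h = h.leaky_relu(0.2)
        skips = [(h, mask)]
        for enc in self.encoders:
            h, mask = enc(h, mask)
            h = h.leaky_relu(0.2)
            skips.append((h, mask))
        skips.pop()  # deepest level is the current state, not a skip
        for dec in self.decoders:
            h = h.upsample2()
            mask = mask.repeat(2, axis=2).repeat(2, axis=3)
            s_h, s_m = skips.pop()
            h = nn.concat([h, s_h], axis=1)
            mask = np.maximum(mask, s_m)
            h, mask = dec(h, mask)
            h = h.leaky_relu(0.2)
        out, mask = self.out_layer(h, mask)
        return out, mask


class Discriminator:
    """Encoder that maps an image (pair) to the probability of being real."""

    def __init__(self, in_channels: int, rng, base_channels: int = 8):
        C = base_channels
        self.convs = []
        cin = in_channels
        for cout in (C, 2 * C):
            W = Parameter(
                rng.normal(0.0, np.sqrt(2.0 / (cin * 9)), size=(cout, cin, 3, 3))
            )
            b = Parameter(np.zeros(cout))
            self.convs.append((W, b))
            cin = cout
        self.head_W = Parameter(rng.normal(0.0, 0.1, size=(cin, 1)))
        self.head_b = Parameter(np.zeros(1))

    @property
    def params(self):
        ps = []
        for W, b in self.convs:
            ps.extend([W, b])
        return ps + [self.head_W, self.head_b]

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for W, b in self.convs:
            h = nn.conv2d(h, W, b, stride=2).leaky_relu(0.2)
        pooled = h.mean(axis=(2, 3))  # (N, C)
        logit = pooled.matmul(self.head_W) + self.head_b
        return logit.sigmoid()


def generator_forward(pair: ErasedPair, generator: Generator) -> InpaintResult:
    """Run both passes (raw and mirrored) and composite the outputs.

    ``I_outflip`` is returned re-flipped to the raw orientation so the
    flip-consistency loss compares both outputs in a common frame.  Raises
    if the validity mask was not fully filled by the stacked mask updates.
    """
    if pair.M.sum() == 0:
        raise ValueError("mask has no valid pixels")
    if generator.config.use_flip:
        # the mirrored channel supplies validity where only one side is erased
        eff_M = np.maximum(pair.M, pair.M_flip)
    else:
        eff_M = pair.M
    hole_w = _largest_hole_extent(eff_M)
    rf = _receptive_extent(generator.config)
    if hole_w > rf:
        warnings.warn(
            f"largest hole extent {hole_w} px exceeds the generator's"
            f" receptive extent ~{rf} px; the hole may not fill"
        )
    if generator.config.use_flip:
        out_raw, mask_raw = generator.forward(
            pair.I_erased, pair.M, pair.I_erased_flip, pair.M_flip
        )
        out_f, _ = generator.forward(
            pair.I_erased_flip, pair.M_flip, pair.I_erased, pair.M
        )
        out_flip = out_f.flip_lr()
    else:
        # ablation baseline: conventional single-pass inpainting
        out_raw, mask_raw = generator.forward(pair.I_erased, pair.M)
        out_flip = out_raw
    if not np.all(mask_raw > 0):
        raise RuntimeError(
            "hole not filled: final updated mask still has invalid locations"
        )
    M = Tensor(pair.M)
    gt = Tensor(pair.I_gt)
    one_minus = Tensor(1.0 - pair.M)
    comp = M * gt + one_minus * out_raw
    comp_flip = M * gt + one_minus * out_flip
    return InpaintResult(
        I_out=out_raw,
        I_outflip=out_flip,
        I_comp=comp,
        I_comp_flip=comp_flip,
        final_mask=mask_raw,
    )


def _largest_hole_extent(M: np.ndarray) -> int:
    hole = M[:, 0] == 0
    if not hole.any():
        return 0
    extent = 0
    for n in range(hole.shape[0]):
        lab, nlab = ndimage.label(hole[n])
        for sl in ndimage.find_objects(lab):
            extent = max(
                extent, sl[0].stop - sl[0].start, sl[1].stop - sl[1].start
            )
    return extent


def _receptive_extent(config: GeneratorConfig) -> int:
    # each stride-2 level multiplies the reach of a k x k window
    return (config.kernel_size // 2) * 2 ** (config.depth + 2)


# ---------------------------------------------------------------------------
# losses

def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(_to_nchw(x))


def _l1_region(a: Tensor, b: Tensor, region: np.ndarray) -> Tensor:
    count = float(region.sum())
    if count == 0:
        return Tensor(np.float32(0.0))
    return ((a - b).abs() * Tensor(region)).sum() / count


def _perceptual_from_features(fa: Tensor, fb: Tensor) -> Tensor:
    return (fa - fb).abs().mean()


def perceptual_loss(I_out, I_gt, extractor) -> Tensor:
    """Mean L1 distance between extractor features of output and target."""
    return _perceptual_from_features(
        extractor(_wrap(I_out)), extractor(_wrap(I_gt))
    )


def _gram(f: Tensor) -> Tensor:
    n, c, h, w = f.data.shape
    flat = f.reshape(n, c, h * w)
    return flat.matmul(flat.swapaxes(1, 2)) / float(h * w)


def _style_from_features(fa: Tensor, fb: Tensor) -> Tensor:
    c = fa.data.shape[1]
    n = fa.data.shape[0]
    return (_gram(fa) - _gram(fb)).abs().sum() / float(c * c * n)


def style_loss(I_a, I_b, extractor) -> Tensor:
    """L1 distance between channelwise Gram matrices, scaled by 1/C^2."""
    return _style_from_features(extractor(_wrap(I_a)), extractor(_wrap(I_b)))


def tv_loss(I_comp, region: np.ndarray | None = None) -> Tensor:
    """Mean absolute difference of adjacent pixel pairs.

    A pair contributes when both endpoints lie in ``region`` (whole grid if
    None).  Returns 0 when no pair qualifies."""
    x = _wrap(I_comp)
    n, c, h, w = x.data.shape
    if region is None:
        reg = np.ones((n, 1, h, w), dtype=np.float32)
    else:
        reg = _to_nchw(region).astype(np.float32)
    # horizontal pairs: (i, j) with (i, j+1); vertical: (i, j) with (i+1, j)
    wh = (reg[..., :, :-1] * reg[..., :, 1:]).astype(np.float32)
    wv = (reg[..., :-1, :] * reg[..., 1:, :]).astype(np.float32)
    npairs = float(wh.sum() + wv.sum())
    if npairs == 0:
        return Tensor(np.float32(0.0))
    xh = _slice4(x, (slice(None), slice(None), slice(None), slice(0, w - 1)))
    xh2 = _slice4(x, (slice(None), slice(None), slice(None), slice(1, w)))
    xv = _slice4(x, (slice(None), slice(None), slice(0, h - 1), slice(None)))
    xv2 = _slice4(x, (slice(None), slice(None), slice(1, h), slice(None)))
    total = ((xh - xh2).abs() * Tensor(wh)).sum() + (
        (xv - xv2).abs() * Tensor(wv)
    ).sum()
    return total / npairs


def _slice4(x: Tensor, key) -> Tensor:
    out = Tensor(x.data[key], parents=(x,))

    def backward(g):
        if x.requires_grad:
            buf = np.zeros_like(x.data)
            buf[key] = g
            x.grad += buf

    out._backward = backward
    return out


def flip_loss(I_out, I_outflip) -> Tensor:
    """Flip-consistency: mean absolute difference of the two passes'
    outputs, both in raw orientation."""
    return (_wrap(I_out) - _wrap(I_outflip)).abs().mean()


def hole_tv_region(M: np.ndarray, whole_image: bool = False) -> np.ndarray:
    """Penalized region for the TV term: a 1-pixel dilation of the hole."""
    if whole_image:
        return np.ones_like(M)
    hole = M == 0
    out = np.zeros_like(M)
    for n in range(M.shape[0]):
        out[n, 0] = ndimage.binary_dilation(hole[n, 0], iterations=1)
    return out.astype(np.float32)


def inpainting_loss(
    result_out: Tensor,
    result_comp: Tensor,
    pair: ErasedPair,
    weights: LossWeights,
    extractor=None,
    _f_gt: Tensor | None = None,
) -> tuple[Tensor, dict]:
    """The composite reconstruction loss of one generator pass.

    total = w_valid*L_valid + w_erase*L_erase + w_perceptual*L_perceptual
          + w_style*(L_style_out + L_style_comp) + w_tv*L_tv

    ``_f_gt`` lets a caller reuse precomputed extractor features of the
    ground truth (they are identical across the raw and mirrored passes).
    """
    gt = Tensor(pair.I_gt)
    valid = pair.M
    hole = 1.0 - pair.M
    terms: dict[str, Tensor] = {}
    terms["valid"] = _l1_region(result_out, gt, valid)
    terms["erase"] = _l1_region(result_out, gt, hole)
    use_feat = extractor is not None and (
        weights.w_perceptual > 0 or weights.w_style > 0
    )
    if use_feat:
        f_gt = _f_gt if _f_gt is not None else extractor(gt)
        f_out = extractor(result_out)
    if extractor is not None and weights.w_perceptual > 0:
        terms["perceptual"] = _perceptual_from_features(f_out, f_gt)
    else:
        terms["perceptual"] = Tensor(np.float32(0.0))
    if extractor is not None and weights.w_style > 0:
        terms["style_out"] = _style_from_features(f_out, f_gt)
        terms["style_comp"] = _style_from_features(extractor(result_comp), f_gt)
    else:
        terms["style_out"] = Tensor(np.float32(0.0))
        terms["style_comp"] = Tensor(np.float32(0.0))
    terms["tv"] = tv_loss(result_comp, hole_tv_region(pair.M))
    total = (
        terms["valid"] * weights.w_valid
        + terms["erase"] * weights.w_erase
        + terms["perceptual"] * weights.w_perceptual
        + (terms["style_out"] + terms["style_comp"]) * weights.w_style
        + terms["tv"] * weights.w_tv
    )
    return total, terms


def total_generator_loss(
    result: InpaintResult,
    pair: ErasedPair,
    weights: LossWeights,
    discriminator: Discriminator | None = None,
    extractor=None,
) -> tuple[Tensor, dict]:
    """Reconstruction losses of both passes + flip consistency + w_adv *
    (-log D(fake))."""
    f_gt = None
    if extractor is not None and (weights.w_perceptual > 0 or weights.w_style > 0):
        f_gt = extractor(Tensor(pair.I_gt))
    total_raw, terms = inpainting_loss(
        result.I_out, result.I_comp, pair, weights, extractor, _f_gt=f_gt
    )
    terms = {f"raw_{k}": v for k, v in terms.items()}
    total = total_raw
    if result.I_outflip is not result.I_out:  # flip-guided configuration
        total_flip, terms_f = inpainting_loss(
            result.I_outflip, result.I_comp_flip, pair, weights, extractor,
            _f_gt=f_gt,
        )
        lf = flip_loss(result.I_out, result.I_outflip)
        total = total + total_flip + lf
        terms.update({f"flip_{k}": v for k, v in terms_f.items()})
        terms["flip_consistency"] = lf
    if discriminator is not None and weights.w_adv > 0:
        fake = _disc_input(result.I_out, result.I_outflip, discriminator)
        p = discriminator(fake)
        if np.any(p.data <= 0) or np.any(p.data >= 1):
            raise ValueError("discriminator output must lie in (0, 1)")
        adv = -(p.clip(_EPS, 1.0 - _EPS).log().mean())
        terms["adversarial"] = adv
        total = total + adv * weights.w_adv
    return total, terms


def _disc_input(a: Tensor, b: Tensor, discriminator: Discriminator) -> Tensor:
    in_ch = discriminator.convs[0][0].data.shape[1]
    if in_ch == 2:
        return nn.concat([a, b], axis=1)
    return a


def discriminator_loss(d_real: Tensor, d_fake: Tensor) -> Tensor:
    """Binary cross-entropy: -(log(1 - D(fake)) + log(D(real))), with the
    probabilities clamped away from 0/1."""
    pr = _wrap(d_real).clip(_EPS, 1.0 - _EPS)
    pf = _wrap(d_fake).clip(_EPS, 1.0 - _EPS)
    return -((1.0 - pf).log().mean() + pr.log().mean())


# ---------------------------------------------------------------------------
# training

@dataclass
class InpaintingModel:
    generator: Generator
    discriminator: Discriminator
    config: GeneratorConfig
    weights: LossWeights
    extractor: FixedConvExtractor | None

    def inpaint(self, image: np.ndarray, erase_mask: np.ndarray) -> np.ndarray:
        """Composite inpainted image: ground truth on valid pixels, network
        output inside the erased region."""
        pair = make_erased_pair(image, erase_mask)
        res = generator_forward(pair, self.generator)
        comp = res.I_comp.data
        if image.ndim == 2:
            return comp[0, 0]
        return comp[:, 0]


def train(
    pairs: ErasedPair | list,
    config: GeneratorConfig = GeneratorConfig(),
    weights: LossWeights = LossWeights(),
    epochs: int = 10,
    seed: int = 0,
    batch_size: int = 16,
    lr: float = 2e-3,
) -> tuple[InpaintingModel, "pd.DataFrame"]:
    """Alternating adversarial training: per batch one generator update
    (on total_generator_loss) then one discriminator update (on the BCE
    loss with the generator output detached).  Deterministic given seed in
    single-threaded execution.

    ``pairs`` is an :class:`ErasedPair` whose arrays hold the whole stacked
    dataset, or a list of (image, erase_mask) tuples.
    """
    import pandas as pd

    if isinstance(pairs, list):
        imgs = np.stack([np.asarray(p[0], np.float32) for p in pairs])
        masks = np.stack([np.asarray(p[1], np.float32) for p in pairs])
        pairs = make_erased_pair(imgs, masks)
    n = pairs.I_gt.shape[0]
    if n == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    gen = Generator(config, rng)
    disc = Discriminator(2 if config.use_flip else 1, rng)
    extractor = (
        FixedConvExtractor(seed=1234) if config.extractor == "fixed-random" else None
    )
    opt_g = nn.Adam(gen.params, lr=lr)
    opt_d = nn.Adam(disc.params, lr=lr)
    history = []
    n_updates_g = n_updates_d = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_terms: dict[str, list] = {}
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            batch = ErasedPair(
                I_gt=pairs.I_gt[idx],
                M=pairs.M[idx],
                I_erased=pairs.I_erased[idx],
                I_erased_flip=pairs.I_erased_flip[idx],
                M_flip=pairs.M_flip[idx],
            )
            # generator step
            res = generator_forward(batch, gen)
            g_total, terms = total_generator_loss(
                res, batch, weights, disc, extractor
            )
            if not np.isfinite(g_total.data):
                bad = [k for k, v in terms.items() if not np.isfinite(v.data)]
                raise RuntimeError(f"non-finite generator loss; terms: {bad}")
            g_total.backward()
            opt_g.step()
            n_updates_g += 1
            # discriminator step on detached fakes
            fake = _disc_input(
                res.I_out.detach(), res.I_outflip.detach(), disc
            )
            real = _disc_input(
                Tensor(batch.I_gt), Tensor(batch.I_gt_flip), disc
            )
            d_loss = discriminator_loss(disc(real), disc(fake))
            if not np.isfinite(d_loss.data):
                raise RuntimeError("non-finite discriminator loss")
            d_loss.backward()
            opt_d.step()
            n_updates_d += 1
            for k, v in terms.items():
                ep_terms.setdefault(k, []).append(float(v.data))
            ep_terms.setdefault("g_total", []).append(float(g_total.data))
            ep_terms.setdefault("d_loss", []).append(float(d_loss.data))
        row = {"epoch": epoch}
        row.update({k: float(np.mean(v)) for k, v in ep_terms.items()})
        history.append(row)
    log = pd.DataFrame(history)
    log.attrs["n_updates_g"] = n_updates_g
    log.attrs["n_updates_d"] = n_updates_d
    model = InpaintingModel(gen, disc, config, weights, extractor)
    return model, log


# ---------------------------------------------------------------------------
# evaluation

def evaluate(pred: np.ndarray, gt: np.ndarray) -> dict:
    """PSNR (dB, range-1 convention), SSIM (11x11 Gaussian window), mean
    absolute error and mean squared error.  Identical images report PSNR as
    +inf."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt must share a grid")
    mse = float(np.mean((pred - gt) ** 2))
    if mse == 0:
        psnr = float("inf")
    else:
        psnr = float(peak_signal_noise_ratio(gt, pred, data_range=1.0))
    ssim = float(
        structural_similarity(
            gt,
            pred,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            win_size=11,
        )
    )
    return {
        "psnr": psnr,
        "ssim": ssim,
        "l1": float(np.mean(np.abs(pred - gt))),
        "l2": mse,
    }


# ---------------------------------------------------------------------------
# checkpointing

def save_model(model: InpaintingModel, path: str) -> None:
    """Single-file checkpoint (.npz) with the config embedded."""
    arrays = {}
    for i, p in enumerate(model.generator.params):
        arrays[f"g_{i}"] = p.data
    for i, p in enumerate(model.discriminator.params):
        arrays[f"d_{i}"] = p.data
    meta = json.dumps(
        {"config": asdict(model.config), "weights": asdict(model.weights)}
    )
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path: str) -> InpaintingModel:
    data = np.load(path)
    meta = json.loads(bytes(data["_meta"]).decode())
    config = GeneratorConfig(**meta["config"])
    weights = LossWeights(**meta["weights"])
    rng = np.random.default_rng(0)
    gen = Generator(config, rng)
    disc = Discriminator(2 if config.use_flip else 1, rng)
    for i, p in enumerate(gen.params):
        p.data = data[f"g_{i}"].astype(np.float32)
    for i, p in enumerate(disc.params):
        p.data = data[f"d_{i}"].astype(np.float32)
    extractor = (
        FixedConvExtractor(seed=1234) if config.extractor == "fixed-random" else None
    )
    return InpaintingModel(gen, disc, config, weights, extractor)
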
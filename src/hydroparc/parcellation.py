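"""Inpainting-mediated atlas parcellation.

Direct nonrigid registration of a healthy atlas template onto a severely
deformed, lesion-eroded brain tends to fail around the abnormality.  The
pipeline here goes through the inpainted image instead:

1. erase the abnormal region and inpaint it, giving a pseudo-normal image
   I_N for the original image I_T;
2. produce a brain mask on I_N, warp it onto I_T through the nonrigid
   registration I_N -> I_T, and skull-strip both images;
3. register atlas -> stripped inpainted image and stripped inpainted ->
   stripped original, compose the two deformation fields, and warp the
   atlas label map onto the original T1 grid;
4. rigidly register the stripped T1 to the mean functional image and carry
   the labels onto the fMRI grid.

All fields are dense voxel-space displacements on the fixed grid with
pull-back sampling: ``warped(x) = moving(x + u(x))``.  Label maps are
always resampled with nearest-neighbour interpolation.

The built-in nonrigid optimizer is a multi-resolution (3-level)
demons-style gradient descent on intensity MSE — adequate at phantom
scale; any external registration tool can stand behind the same
field-returning contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.exposure import match_histograms

from .synthetic_data import AtlasBundle

__all__ = [
    "DeformationField",
    "RigidTransform",
    "RegistrationConfig",
    "ParcellationResult",
    "AtlasBundle",
    "register_nonrigid",
    "register_rigid",
    "compose",
    "warp",
    "brain_mask",
    "propagate_brain_mask",
    "parcellate",
    "dice_per_label",
]


@dataclass
class DeformationField:
    """Dense displacement on the fixed grid, in voxel units.

    ``disp[0]`` is the row displacement, ``disp[1]`` the column
    displacement; sampling the moving image at ``x + disp(x)`` yields the
    warped image on the fixed grid.
    """

    disp: np.ndarray  # (2, H, W)

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=np.float64)
        if self.disp.ndim != 3 or self.disp.shape[0] != 2:
            raise ValueError("displacement must have shape (2, H, W)")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self):
        return self.disp.shape[1:]

    @classmethod
    def identity(cls, shape) -> "DeformationField":
        return cls(np.zeros((2,) + tuple(shape)))

    def mean_magnitude(self) -> float:
        return float(np.mean(np.hypot(self.disp[0], self.disp[1])))


@dataclass
class RigidTransform:
    """2-D rotation + translation in homogeneous voxel coordinates.

    Maps fixed-grid coordinates to moving-image coordinates (pull-back,
    same convention as :class:`DeformationField`).
    """

    matrix: np.ndarray  # (3, 3)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        R = self.matrix[:2, :2]
        if not np.allclose(R.T @ R, np.eye(2), atol=1e-6):
            raise ValueError("rotation block must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block must have determinant +1")

    @classmethod
    def from_params(cls, angle_rad: float, t_row: float, t_col: float,
                    center=(0.0, 0.0)) -> "RigidTransform":
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        R = np.array([[c, -s], [s, c]])
        cy = np.asarray(center, dtype=np.float64)
        t = cy - R @ cy + np.array([t_row, t_col])
        M = np.eye(3)
        M[:2, :2] = R
        M[:2, 2] = t
        return cls(M)

    @property
    def angle(self) -> float:
        return float(np.arctan2(self.matrix[1, 0], self.matrix[0, 0]))

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:2, 2].copy()

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix))


# ---------------------------------------------------------------------------
# warping and composition

def _grid(shape):
    return np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)


def warp(image: np.ndarray, transform, interpolation: str = "linear") -> np.ndarray:
    """Resample ``image`` onto the fixed grid of ``transform``.

    ``interpolation`` is "linear" or "nearest"; integer-valued label maps
    must use "nearest" (requesting linear raises).  Out-of-bounds samples
    fill with 0 / background.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    img = np.asarray(image)
    is_labels = np.issubdtype(img.dtype, np.integer)
    if is_labels and interpolation == "linear":
        raise ValueError("label maps must be warped with nearest interpolation")
    if isinstance(transform, DeformationField):
        if transform.shape != img.shape:
            raise ValueError(
                f"field grid {transform.shape} does not match image {img.shape}"
            )
        rr, cc = _grid(img.shape)
        coords = np.stack([rr + transform.disp[0], cc + transform.disp[1]])
    elif isinstance(transform, RigidTransform):
        rr, cc = _grid(img.shape)
        M = transform.matrix
        coords = np.stack(
            [
                M[0, 0] * rr + M[0, 1] * cc + M[0, 2],
                M[1, 0] * rr + M[1, 1] * cc + M[1, 2],
            ]
        )
    else:
        raise TypeError(f"unsupported transform type {type(transform)!r}")
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.map_coordinates(
        img.astype(np.float64) if not is_labels else img,
        coords,
        order=order,
        mode="constant",
        cval=0,
    )
    return out.astype(img.dtype) if is_labels else out


def compose(first: DeformationField, second: DeformationField) -> DeformationField:
    """Functional composition: applying the result equals warping by
    ``first`` then by ``second``.

    ``composed(x) = first(x + second(x)) + second(x)`` — the first field is
    interpolated at the positions the second field maps to, not naively
    added.
    """
    if first.shape != second.shape:
        raise ValueError(
            f"grid mismatch: first {first.shape} vs second {second.shape}"
        )
    rr, cc = _grid(second.shape)
    coords = np.stack([rr + second.disp[0], cc + second.disp[1]])
    interp = np.stack(
        [
            ndimage.map_coordinates(
                first.disp[a], coords, order=1, mode="nearest"
            )
            for a in range(2)
        ]
    )
    return DeformationField(interp + second.disp)


# ---------------------------------------------------------------------------
# registration

@dataclass(frozen=True)
class RegistrationConfig:
    levels: int = 3
    iterations: tuple = (60, 60, 40)  # finest last
    step: float = 1.5
    sigma_fluid: float = 1.0
    sigma_elastic: float = 1.5


def _downsample(img, factor):
    if factor == 1:
        return img
    return ndimage.zoom(img, 1.0 / factor, order=1)


def _mse(a, b):
    return float(np.mean((a - b) ** 2))


def register_nonrigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    config: RegistrationConfig = RegistrationConfig(),
    exclude_mask: np.ndarray | None = None,
) -> DeformationField:
    """Demons-style multi-resolution MSE registration.

    Returns the displacement field on the fixed grid.  ``exclude_mask``
    (1 = excluded, on the fixed grid) removes a known-unreliable region —
    e.g. an erased abnormality — from the similarity force; the field
    there comes only from the elastic smoothing of its surroundings.  If
    the optimizer fails to improve on the identity alignment the identity
    field is returned with a warning naming the final similarity.
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if moving.ndim != fixed.ndim:
        raise ValueError("moving and fixed must share dimensionality")
    if exclude_mask is not None and np.asarray(exclude_mask).shape != fixed.shape:
        raise ValueError("exclude_mask must live on the fixed grid")
    factors = [2 ** (config.levels - 1 - l) for l in range(config.levels)]
    u = None
    for level, factor in enumerate(factors):
        f_l = _downsample(fixed, factor)
        m_l = _downsample(moving, factor)
        if exclude_mask is not None:
            keep_l = _downsample(
                1.0 - np.asarray(exclude_mask, dtype=np.float64), factor
            ) > 0.5
        else:
            keep_l = None
        if u is None:
            u = np.zeros((2,) + f_l.shape)
        else:
            u = np.stack(
                [
                    ndimage.zoom(u[a], np.array(f_l.shape) / np.array(u.shape[1:]),
                                 order=1)
                    for a in range(2)
                ]
            ) * 2.0
        rr, cc = _grid(f_l.shape)
        n_iter = config.iterations[min(level, len(config.iterations) - 1)]
        for _ in range(n_iter):
            coords = np.stack([rr + u[0], cc + u[1]])
            warped = ndimage.map_coordinates(m_l, coords, order=1, mode="nearest")
            diff = f_l - warped
            gy, gx = np.gradient(warped)
            denom = gy ** 2 + gx ** 2 + diff ** 2 + 1e-9
            vy = diff * gy / denom
            vx = diff * gx / denom
            if keep_l is not None:
                vy *= keep_l
                vx *= keep_l
            vy = ndimage.gaussian_filter(vy, config.sigma_fluid)
            vx = ndimage.gaussian_filter(vx, config.sigma_fluid)
            u[0] += config.step * vy
            u[1] += config.step * vx
            u[0] = ndimage.gaussian_filter(u[0], config.sigma_elastic)
            u[1] = ndimage.gaussian_filter(u[1], config.sigma_elastic)
    field = DeformationField(u)
    final = _mse(warp(moving, field), fixed)
    identity = _mse(moving, fixed)
    if final > identity:
        warnings.warn(
            f"nonrigid registration did not improve alignment"
            f" (MSE {final:.5f} vs identity {identity:.5f}); returning identity"
        )
        return DeformationField.identity(fixed.shape)
    return field


def register_rigid(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """6-DOF-style rigid registration (2-D: rotation + translation) by
    Powell search on intensity MSE, coarse-to-fine."""
    from scipy.optimize import minimize

    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    center = (np.asarray(fixed.shape, dtype=np.float64) - 1) / 2.0

    x0 = np.zeros(3)
    for factor in (2, 1):
        f_l = _downsample(fixed, factor)
        m_l = _downsample(moving, factor)
        c_l = (np.asarray(f_l.shape, dtype=np.float64) - 1) / 2.0

        def cost(params):
            t = RigidTransform.from_params(
                params[0], params[1], params[2], center=c_l
            )
            return _mse(warp(m_l, t), f_l)

        res = minimize(
            cost,
            x0,
            method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 400},
        )
        x0 = res.x
        if factor == 2:
            x0[1:] *= 2.0  # translations into full-resolution voxels
    t = RigidTransform.from_params(x0[0], x0[1], x0[2], center=center)
    if _mse(warp(moving, t), fixed) > _mse(moving, fixed):
        warnings.warn("rigid registration did not improve alignment; identity kept")
        return RigidTransform.from_params(0.0, 0.0, 0.0)
    return t


# ---------------------------------------------------------------------------
# skull stripping and the pipeline

def brain_mask(image: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Built-in brain-mask provider: intensity threshold, largest connected
    component, morphological closing and hole filling.  Sufficient for
    phantoms; any external skull-stripper can replace it (the pipeline only
    needs a binary mask on the same grid)."""
    fg = np.asarray(image) > threshold
    lab, n = ndimage.label(fg)
    if n == 0:
        return np.zeros_like(fg, dtype=np.uint8)
    sizes = ndimage.sum_labels(fg, lab, index=np.arange(1, n + 1))
    keep = lab == (1 + int(np.argmax(sizes)))
    keep = ndimage.binary_closing(keep, iterations=2)
    keep = ndimage.binary_fill_holes(keep)
    return keep.astype(np.uint8)


def propagate_brain_mask(I_N, I_T, M_N, config=RegistrationConfig(),
                         exclude_mask=None):
    """Warp the inpainted image's brain mask onto the original image:
    ``M_T = warp(M_N, phi_{I_N -> I_T})``; returns (M_T, stripped I_T)."""
    M_N = np.asarray(M_N)
    if M_N.shape != np.asarray(I_N).shape:
        raise ValueError("M_N must live on I_N's grid")
    phi = register_nonrigid(I_N, I_T, config, exclude_mask=exclude_mask)
    M_T = warp(M_N.astype(np.int32), phi, "nearest").astype(np.uint8)
    if M_T.sum() == 0:
        raise ValueError("propagated brain mask is empty")
    return M_T, np.asarray(I_T, dtype=np.float64) * M_T


@dataclass
class ParcellationResult:
    I_N: np.ndarray
    M_N: np.ndarray
    M_T: np.ndarray
    I_N_stripped: np.ndarray
    I_T_stripped: np.ndarray
    L_T: np.ndarray
    L_F: np.ndarray | None
    field_atlas_to_T: DeformationField
    rigid_T_to_F: RigidTransform | None


def parcellate(
    I_T: np.ndarray,
    erase_mask: np.ndarray,
    inpaint_model,
    atlas: AtlasBundle,
    fmri_mean: np.ndarray | None = None,
    no_inpaint: bool = False,
    histogram_match: bool = True,
    config: RegistrationConfig = RegistrationConfig(),
) -> ParcellationResult:
    """The full label-transfer pipeline (atlas -> T1 grid -> fMRI grid).

    ``erase_mask`` (1 = abnormal) marks the manually identified abnormal
    region.  ``inpaint_model`` is anything with an ``inpaint(image, mask)``
    method.  ``no_inpaint`` bypasses the inpainting mediation and registers
    the atlas directly onto the original image (the ablation branch).
    ``fmri_mean=None`` skips the final rigid stage (L_F is then None).
    """
    I_T = np.asarray(I_T, dtype=np.float64)
    stage = "inpainting"
    try:
        if no_inpaint:
            I_N = I_T.copy()
        else:
            I_N = np.asarray(
                inpaint_model.inpaint(
                    I_T.astype(np.float32), np.asarray(erase_mask)
                ),
                dtype=np.float64,
            )
        stage = "brain masking"
        M_N = brain_mask(I_N)
        if M_N.sum() == 0:
            raise ValueError("brain mask of the inpainted image is empty")
        I_N_s = I_N * M_N
        erase = np.asarray(erase_mask) if erase_mask is not None else None
        stage = "brain-mask propagation"
        if no_inpaint or np.allclose(I_N, I_T):
            M_T, I_T_s = M_N.copy(), I_T * M_N
        else:
            M_T, I_T_s = propagate_brain_mask(
                I_N, I_T, M_N, config, exclude_mask=erase
            )
        stage = "atlas registration"
        atlas_img = np.asarray(atlas.image, dtype=np.float64)
        if histogram_match:
            atlas_img = match_histograms(atlas_img, I_N_s)
        phi_A_to_N = register_nonrigid(atlas_img, I_N_s, config)
        if no_inpaint:
            phi_A_to_T = phi_A_to_N  # direct: I_N^S is I_T^S
        else:
            # the erased region is known-abnormal: it carries synthetic
            # tissue in I_N^S and the abnormality in I_T^S, so it is
            # excluded from the similarity force of this step
            phi_N_to_T = register_nonrigid(
                I_N_s, I_T_s, config, exclude_mask=erase
            )
            phi_A_to_T = compose(phi_A_to_N, phi_N_to_T)
        stage = "label warping"
        L_T = warp(np.asarray(atlas.labels, dtype=np.int32), phi_A_to_T, "nearest")
        L_F = None
        rigid = None
        if fmri_mean is not None:
            stage = "rigid T1->fMRI registration"
            rigid = register_rigid(I_T_s, np.asarray(fmri_mean, dtype=np.float64))
            L_F = warp(L_T, rigid, "nearest")
    except Exception as err:
        raise RuntimeError(f"parcellation failed at stage: {stage}") from err
    return ParcellationResult(
        I_N=I_N,
        M_N=M_N,
        M_T=M_T,
        I_N_stripped=I_N_s,
        I_T_stripped=I_T_s,
        L_T=L_T,
        L_F=L_F,
        field_atlas_to_T=phi_A_to_T,
        rigid_T_to_F=rigid,
    )


def dice_per_label(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Dice overlap per nonzero label present in the ground truth."""
    out = {}
    for lab in np.unique(truth):
        if lab == 0:
            continue
        p = pred == lab
        t = truth == lab
        denom = p.sum() + t.sum()
        out[int(lab)] = float(2.0 * np.logical_and(p, t).sum() / denom) if denom else 0.0
    return out
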
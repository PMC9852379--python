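"""Synthetic data generators for every stage of the pipeline.

Real post-traumatic hydrocephalus scans cannot be redistributed, so the
package ships generators that emulate the properties each stage relies on:

* 2-D brain-like phantoms that are exactly left-right mirror symmetric
  unless a unilateral lesion or asymmetry noise is requested — the symmetry
  prior the inpainting network exploits;
* random erase masks marking "abnormal" regions to remove before inpainting;
* BOLD-like time series with a planted region-by-region covariance, so that
  functional-connectivity estimation has a known ground truth;
* cohorts with a sparse planted linear relation between connectivity
  features and a consciousness score, plus planted before/after shifts in
  small-worldness for a favorable and an unfavorable outcome group.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Lesion",
    "PhantomSpec",
    "CohortSpec",
    "Cohort",
    "AtlasBundle",
    "make_symmetric_phantom",
    "make_erase_mask",
    "make_atlas",
    "simulate_bold",
    "simulate_cohort",
]


@dataclass(frozen=True)
class Lesion:
    """An elliptical unilateral abnormality.

    ``intensity_shift`` is added inside the ellipse; ``deform_amplitude``
    (pixels) optionally pushes tissue radially outward from the centre,
    emulating the mass effect of a deformed ventricle rather than a pure
    intensity erosion.  The whole effect is confined to the ellipse's
    bounding box.
    """

    center: tuple[int, int]
    radii: tuple[float, float]
    intensity_shift: float = -0.3
    deform_amplitude: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    image_size: int = 64
    n_regions: int = 12
    lesion: Lesion | None = None
    asymmetry_noise: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class CohortSpec:
    """Planted-model cohort: y = X w* + noise, two scans per patient."""

    n_patients: int = 28
    n_features: int = 4005
    w_star: np.ndarray | None = None
    n_nonzero: int = 5
    noise_sd: float = 0.0
    sigma_shift: float = 0.0
    dsigma_sd: float = 1.0
    seed: int = 0


@dataclass
class Cohort:
    X: np.ndarray            # (2 * n_patients, n_features), scan rows
    y: np.ndarray            # (2 * n_patients,)
    patient_ids: np.ndarray  # per scan row
    timepoints: np.ndarray   # per scan row, "before" | "after"
    groups: np.ndarray       # per patient, "favorable" | "unfavorable"
    dsigma: np.ndarray       # per patient planted Δσ draw
    w_star: np.ndarray

    @property
    def n_patients(self) -> int:
        return len(self.groups)

    def timepoint_matrix(self, timepoint: str) -> np.ndarray:
        """One row per patient for a single timepoint."""
        return self.X[self.timepoints == timepoint]

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "patient_id": self.patient_ids,
            "timepoint": self.timepoints,
            "group": self.groups[self.patient_ids],
            "crs_r": self.y,
        }
        df = pd.DataFrame(cols)
        feat = pd.DataFrame(
            self.X, columns=[f"feature_{j}" for j in range(self.X.shape[1])]
        )
        return pd.concat([df, feat], axis=1)


@dataclass
class AtlasBundle:
    """Template intensity image, its label map and a region-name table."""

    image: np.ndarray
    labels: np.ndarray
    names: pd.DataFrame  # columns: label_id, name

    @property
    def n_regions(self) -> int:
        return int(len(self.names))


# ---------------------------------------------------------------------------
# phantoms

def _head_mask(size: int) -> np.ndarray:
    r, c = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = (size - 1) / 2.0
    cx = (size - 1) / 2.0
    return ((r - cy) / (0.46 * size)) ** 2 + ((c - cx) / (0.40 * size)) ** 2 <= 1.0


def make_symmetric_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate a brain-like intensity image and its planted label map.

    With no lesion and ``asymmetry_noise == 0`` the image equals its
    left-right mirror exactly, and labels are placed mirror symmetrically:
    left-hemisphere labels ``1..n_pairs`` map to right-hemisphere labels
    ``n_pairs+1..2*n_pairs``; an odd ``n_regions`` adds one midline region.
    Intensities are normalized to [0, 1].
    """
    if spec.image_size < 32:
        raise ValueError("image_size must be >= 32")
    if spec.n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    size = spec.image_size
    rng = np.random.default_rng(spec.seed)
    brain = _head_mask(size)
    half = size // 2

    n_pairs = spec.n_regions // 2
    n_mid = spec.n_regions % 2

    # Voronoi-style parcels on the left half, mirrored to the right.
    left_cols = np.arange(half)
    rows, cols = np.nonzero(brain[:, :half])
    if len(rows) < n_pairs:
        raise ValueError("too few brain pixels for the requested regions")
    seed_idx = rng.choice(len(rows), size=n_pairs, replace=False)
    seeds = np.stack([rows[seed_idx], cols[seed_idx]], axis=1).astype(np.float64)
    rr, cc = np.mgrid[0:size, 0:half].astype(np.float64)
    d2 = (rr[None] - seeds[:, 0, None, None]) ** 2 + (
        cc[None] - seeds[:, 1, None, None]
    ) ** 2
    left_assign = np.argmin(d2, axis=0) + 1  # labels 1..n_pairs

    labels = np.zeros((size, size), dtype=np.int32)
    labels[:, :half][brain[:, :half]] = left_assign[brain[:, :half]]
    # mirror: column j -> size-1-j
    mirrored = labels[:, :half][:, ::-1]
    right = np.where(mirrored > 0, mirrored + n_pairs, 0)
    labels[:, size - half :] = right

    if n_mid:
        # symmetric midline ellipse region overriding its neighbourhood
        r, c = np.mgrid[0:size, 0:size].astype(np.float64)
        cy, cx = (size - 1) / 2.0, (size - 1) / 2.0
        mid = ((r - cy) / (0.28 * size)) ** 2 + ((c - cx) / (0.07 * size)) ** 2 <= 1.0
        labels[mid & brain] = spec.n_regions

    # pairwise-shared region intensities keep the image mirror symmetric
    pair_vals = rng.uniform(0.30, 0.90, size=n_pairs)
    mid_val = rng.uniform(0.30, 0.90)
    image = np.zeros((size, size), dtype=np.float64)
    for p in range(n_pairs):
        image[labels == p + 1] = pair_vals[p]
        image[labels == p + 1 + n_pairs] = pair_vals[p]
    if n_mid:
        image[labels == spec.n_regions] = mid_val

    # smooth symmetric texture, built on the left half then mirrored
    tex_left = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, size=(size, half)), sigma=3.0
    )
    tex = np.zeros((size, size))
    tex[:, :half] = tex_left
    tex[:, size - half :] = tex_left[:, ::-1]
    if size % 2 == 1:
        mid_col = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=size), 3.0)
        tex[:, half] = mid_col
    image += 0.05 * tex * brain

    image = np.clip(image, 0.0, 1.0)

    if spec.asymmetry_noise > 0:
        image = np.clip(
            image + rng.normal(0.0, spec.asymmetry_noise, size=image.shape) * brain,
            0.0,
            1.0,
        )

    if spec.lesion is not None:
        image, labels = _apply_lesion(image, labels, spec.lesion, rng)

    return image.astype(np.float32), labels


def _apply_lesion(image, labels, lesion: Lesion, rng):
    size = image.shape[0]
    (cy, cx), (ry, rx) = lesion.center, lesion.radii
    if (
        cy - ry < 0 or cy + ry > size - 1 or cx - rx < 0 or cx + rx > size - 1
    ):
        raise ValueError(
            f"lesion bounding box [{cy - ry}, {cy + ry}] x [{cx - rx}, {cx + rx}]"
            f" exceeds the {size}x{size} image bounds"
        )
    r, c = np.mgrid[0:size, 0:size].astype(np.float64)
    e = ((r - cy) / ry) ** 2 + ((c - cx) / rx) ** 2
    inside = e <= 1.0

    if lesion.deform_amplitude > 0:
        # compact radial push, zero at and beyond the ellipse boundary
        w = np.clip(1.0 - e, 0.0, 1.0)
        dr = r - cy
        dc = c - cx
        norm = np.hypot(dr, dc) + 1e-9
        ur = lesion.deform_amplitude * w * dr / norm
        uc = lesion.deform_amplitude * w * dc / norm
        # pull-back sampling: value at x taken from x - u(x)
        coords = np.stack([r - ur, c - uc])
        image = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
        labels = ndimage.map_coordinates(labels, coords, order=0, mode="nearest")

    image = image.copy()
    image[inside] = np.clip(image[inside] + lesion.intensity_shift, 0.0, 1.0)
    return image, labels


def make_atlas(image_size: int = 64, n_regions: int = 90, seed: int = 0) -> AtlasBundle:
    """A phantom-family atlas: template image + label map + name table.

    Defaults follow the 90-region cortical/subcortical convention (bilateral
    pairs, cerebellum excluded) used for whole-brain parcellation.
    """
    img, lab = make_symmetric_phantom(
        PhantomSpec(image_size=image_size, n_regions=n_regions, seed=seed)
    )
    n_pairs = n_regions // 2
    names = []
    for lid in range(1, n_regions + 1):
        if n_regions % 2 and lid == n_regions:
            names.append((lid, "Midline_1"))
        elif lid <= n_pairs:
            names.append((lid, f"Region_{lid}_L"))
        else:
            names.append((lid, f"Region_{lid - n_pairs}_R"))
    table = pd.DataFrame(names, columns=["label_id", "name"])
    return AtlasBundle(image=img, labels=lab, names=table)


# ---------------------------------------------------------------------------
# erase masks

def _draw_shape(size, rng, target_area, side):
    kind = rng.choice(["rect", "ellipse", "stroke"])
    mask = np.zeros((size, size), dtype=bool)
    lo, hi = (0, size // 2) if side == "left" else (
        (size // 2, size) if side == "right" else (0, size)
    )
    cy = rng.integers(size // 8, size - size // 8)
    cx = rng.integers(lo + 2, hi - 2)
    if kind == "rect":
        aspect = rng.uniform(0.5, 2.0)
        h = max(2, int(np.sqrt(target_area * aspect)))
        w = max(2, int(np.sqrt(target_area / aspect)))
        r0, r1 = np.clip([cy - h // 2, cy + h // 2 + 1], 0, size)
        c0, c1 = np.clip([cx - w // 2, cx + w // 2 + 1], lo, hi)
        mask[r0:r1, c0:c1] = True
    elif kind == "ellipse":
        aspect = rng.uniform(0.5, 2.0)
        ry = max(1.5, np.sqrt(target_area * aspect / np.pi))
        rx = max(1.5, np.sqrt(target_area / (aspect * np.pi)))
        r, c = np.mgrid[0:size, 0:size].astype(np.float64)
        mask = ((r - cy) / ry) ** 2 + ((c - cx) / rx) ** 2 <= 1.0
    else:  # stroke: thick random walk
        n_steps = 8
        thickness = max(1.0, np.sqrt(target_area / (n_steps * 3.0)))
        pos = np.array([cy, cx], dtype=np.float64)
        r, c = np.mgrid[0:size, 0:size].astype(np.float64)
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(n_steps):
            mask |= (r - pos[0]) ** 2 + (c - pos[1]) ** 2 <= thickness ** 2
            ang += rng.normal(0, 0.6)
            pos += 2.0 * thickness * np.array([np.sin(ang), np.cos(ang)])
            pos[0] = np.clip(pos[0], 0, size - 1)
            pos[1] = np.clip(pos[1], lo, hi - 1)
    if side is not None:
        keep = np.zeros_like(mask)
        keep[:, lo:hi] = True
        mask &= keep
    return mask


def make_erase_mask(
    image_size: int,
    n_shapes: int = 3,
    coverage_range: tuple[float, float] = (0.1, 0.3),
    seed: int = 0,
    side: str | None = None,
    max_retries: int = 200,
) -> np.ndarray:
    """Random erase-region mask (1 = erased) built from rectangles,
    ellipses and strokes; total 1-fraction lands inside ``coverage_range``.

    ``side`` restricts the erased shapes to one hemisphere ("left"/"right"),
    emulating unilateral abnormalities.
    """
    lo, hi = coverage_range
    if not (0 < lo < hi < 0.5):
        raise ValueError("coverage_range must satisfy 0 < lo < hi < 0.5")
    if side not in (None, "left", "right"):
        raise ValueError("side must be None, 'left' or 'right'")
    if n_shapes == 0:
        return np.zeros((image_size, image_size), dtype=np.uint8)

    rng = np.random.default_rng(seed)
    target = (lo + hi) / 2.0 * image_size ** 2
    achieved = 0.0
    for _ in range(max_retries):
        mask = np.zeros((image_size, image_size), dtype=bool)
        for _ in range(n_shapes):
            mask |= _draw_shape(image_size, rng, target / n_shapes, side)
        achieved = mask.mean()
        if lo <= achieved <= hi:
            return mask.astype(np.uint8)
        # steer the per-shape target toward the requested band
        target *= np.clip((lo + hi) / 2.0 / max(achieved, 1e-6), 0.5, 2.0)
    raise RuntimeError(
        f"could not reach coverage in [{lo}, {hi}] after {max_retries} retries"
        f" (last achieved {achieved:.4f})"
    )


# ---------------------------------------------------------------------------
# BOLD and cohorts

def simulate_bold(
    label_map: np.ndarray,
    region_cov: np.ndarray,
    n_timepoints: int = 190,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """BOLD-like series: every voxel of region r carries that region's
    latent Gaussian series (drawn from ``region_cov``) plus voxelwise noise.

    Returns an array of shape ``label_map.shape + (n_timepoints,)``.
    Background (label 0) voxels carry noise only.
    """
    cov = np.asarray(region_cov, dtype=np.float64)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("region_cov must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("region_cov must be symmetric")
    evals = np.linalg.eigvalsh(cov)
    if evals.min() < -1e-8:
        raise ValueError(
            f"region_cov must be positive semi-definite (min eigenvalue {evals.min():.3g})"
        )
    n_regions = cov.shape[0]
    if label_map.max() > n_regions:
        raise ValueError("label map contains labels beyond region_cov's size")

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_regions))
    latent = chol @ rng.standard_normal((n_regions, n_timepoints))

    out = np.zeros(label_map.shape + (n_timepoints,), dtype=np.float64)
    for r in range(1, n_regions + 1):
        out[label_map == r] = latent[r - 1]
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=out.shape)
    return out


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Cohort with a sparse planted score model and planted Δσ contrast.

    Each patient contributes a "before" and an "after" scan row; scores
    follow ``y = X w* + eps``.  Patients in the favorable group draw their
    small-worldness change Δσ from N(-sigma_shift, dsigma_sd²), the
    unfavorable group from N(+sigma_shift, dsigma_sd²) — the direction the
    drainage-outcome contrast plants.
    """
    if spec.n_patients < 4:
        raise ValueError("n_patients must be >= 4")
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(spec.seed)

    p = spec.n_features
    if spec.w_star is not None:
        w_star = np.asarray(spec.w_star, dtype=np.float64)
        if w_star.shape != (p,):
            raise ValueError("w_star length must equal n_features")
        if np.count_nonzero(w_star) > p:
            raise ValueError("w_star sparsity exceeds n_features")
    else:
        w_star = np.zeros(p)
        support = rng.choice(p, size=min(spec.n_nonzero, p), replace=False)
        w_star[support] = rng.uniform(0.5, 1.5, size=len(support)) * rng.choice(
            [-1.0, 1.0], size=len(support)
        )

    n_scans = 2 * spec.n_patients
    X = rng.standard_normal((n_scans, p))
    y = X @ w_star
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n_scans)

    # favorable/unfavorable split in the study's 17:11 proportion
    n_fav = int(round(spec.n_patients * 17 / 28))
    n_fav = min(max(n_fav, 2), spec.n_patients - 2)
    groups = np.array(
        ["favorable"] * n_fav + ["unfavorable"] * (spec.n_patients - n_fav)
    )
    rng.shuffle(groups)
    shift = np.where(groups == "favorable", -spec.sigma_shift, spec.sigma_shift)
    dsigma = rng.normal(shift, spec.dsigma_sd)

    patient_ids = np.repeat(np.arange(spec.n_patients), 2)
    timepoints = np.tile(np.array(["before", "after"]), spec.n_patients)
    # interleave rows so scan row order is (p0 before, p0 after, p1 before, ...)
    return Cohort(
        X=X,
        y=y,
        patient_ids=patient_ids,
        timepoints=timepoints,
        groups=groups,
        dsigma=dsigma,
        w_star=w_star,
    )
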
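"""ROI signal extraction and functional-connectivity matrices.

A labelled parcellation carries each region's mean BOLD time course; the
functional-connectivity (FC) network is the region-by-region Pearson
correlation matrix.  Thresholding it at a sweep of cutoffs produces the
binary adjacency matrices that the small-world analysis consumes, and the
strict upper triangle of the FC matrix is the per-scan feature vector for
score regression (90 regions -> 90*89/2 = 4005 features).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeseries",
    "FCMatrix",
    "AdjacencySet",
    "DEFAULT_THRESHOLDS",
    "roi_timeseries",
    "fc_matrix",
    "binarize",
    "vectorize_upper",
    "devectorize_upper",
    "feature_pair_names",
]

# ten evenly spaced correlation cutoffs
DEFAULT_THRESHOLDS = tuple(np.round(np.linspace(0.05, 0.50, 10), 2))


@dataclass
class RoiTimeseries:
    data: np.ndarray          # (n_regions_present, n_timepoints)
    region_ids: np.ndarray    # labels actually present, ascending
    missing_regions: list     # labels expected but empty

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]


@dataclass
class FCMatrix:
    values: np.ndarray        # (n, n) symmetric, unit diagonal
    region_ids: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("FC matrix must have unit diagonal")
        if v.min() < -1 - 1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class AdjacencySet:
    """Binary adjacency per threshold: A_ij = 1 iff FC_ij > tau (strict),
    diagonal forced to zero."""

    thresholds: tuple
    matrices: list  # one (n, n) uint8 array per threshold

    def __len__(self):
        return len(self.thresholds)

    def __iter__(self):
        return iter(zip(self.thresholds, self.matrices))


def roi_timeseries(
    fmri: np.ndarray, labels: np.ndarray, expected_labels=None
) -> RoiTimeseries:
    """Mean BOLD time course per labelled region.

    ``fmri`` has the time axis last (spatial shape + (T,)); ``labels`` is
    the integer label map on the same spatial grid.  Labels expected but
    absent (no voxels) are excluded and reported in ``missing_regions``.
    """
    fmri = np.asarray(fmri)
    labels = np.asarray(labels)
    if fmri.shape[:-1] != labels.shape:
        raise ValueError(
            f"fMRI spatial grid {fmri.shape[:-1]} does not match labels"
            f" {labels.shape}"
        )
    present = [int(l) for l in np.unique(labels) if l > 0]
    expected = (
        [int(l) for l in expected_labels] if expected_labels is not None else present
    )
    missing = sorted(set(expected) - set(present))
    rows = []
    kept = []
    flat = fmri.reshape(-1, fmri.shape[-1])
    lab_flat = labels.reshape(-1)
    for l in expected:
        if l in missing:
            continue
        rows.append(flat[lab_flat == l].mean(axis=0))
        kept.append(l)
    return RoiTimeseries(
        data=np.asarray(rows, dtype=np.float64),
        region_ids=np.asarray(kept, dtype=np.int64),
        missing_regions=missing,
    )


def fc_matrix(ts: RoiTimeseries) -> FCMatrix:
    """Pearson correlation between every pair of region time courses."""
    X = np.asarray(ts.data, dtype=np.float64)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    sd = X.std(axis=1)
    bad = np.nonzero(sd == 0)[0]
    if len(bad):
        names = [int(ts.region_ids[i]) for i in bad]
        raise ValueError(
            f"zero-variance time course for region(s) {names}:"
            " correlation undefined"
        )
    r = np.corrcoef(X)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return FCMatrix(values=r, region_ids=ts.region_ids.copy())


def binarize(fc: FCMatrix, thresholds=DEFAULT_THRESHOLDS) -> AdjacencySet:
    """One binary adjacency matrix per threshold (strict >, zero diagonal).

    Negative correlations never exceed a positive cutoff, so they are
    excluded by construction."""
    thresholds = tuple(float(t) for t in thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    mats = []
    for tau in thresholds:
        A = (fc.values > tau).astype(np.uint8)
        np.fill_diagonal(A, 0)
        mats.append(A)
    return AdjacencySet(thresholds=thresholds, matrices=mats)


def vectorize_upper(fc: FCMatrix | np.ndarray) -> np.ndarray:
    """Strict upper triangle in row-major order: (r12, r13, ..., r1n,
    r23, ...); length n(n-1)/2 — 4005 for 90 regions."""
    v = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("input must be square")
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu].copy()


def devectorize_upper(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: rebuild the symmetric matrix
    with unit diagonal."""
    vec = np.asarray(vec)
    if len(vec) != n * (n - 1) // 2:
        raise ValueError(f"vector length {len(vec)} != n(n-1)/2 for n={n}")
    out = np.eye(n)
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


def feature_pair_names(names: pd.DataFrame) -> list:
    """Region-pair names ("A—B") in vectorization order, from an atlas
    name table (columns label_id, name)."""
    ordered = names.sort_values("label_id")["name"].tolist()
    n = len(ordered)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            out.append(f"{ordered[i]}—{ordered[j]}")
    return out
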
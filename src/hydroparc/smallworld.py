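"""Small-world characteristics of binarized FC networks.

For each thresholded adjacency matrix the clustering coefficient C and the
characteristic path length L are normalized by their means over an
ensemble of degree-preserving random networks:

    lambda = L / L_random,   gamma = C / C_random,   sigma = gamma / lambda

A small-world network combines near-random path lengths (lambda ~ 1) with
above-random clustering (gamma > 1), giving sigma > 1.  Per scan, sigma is
averaged across thresholds; per patient, the drainage-outcome analysis
compares delta-sigma = sigma_after - sigma_before between the favorable
and unfavorable groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from .connectivity import AdjacencySet

__all__ = [
    "SmallWorldSummary",
    "clustering_coefficient",
    "characteristic_path_length",
    "random_reference",
    "small_world_summary",
    "group_compare",
]


def _check_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have zero diagonal")
    if not np.isin(A, (0, 1)).all():
        raise ValueError("adjacency must be binary")
    return A.astype(np.float64)


def clustering_coefficient(A: np.ndarray) -> float:
    """Mean nodal clustering: for node i with degree k_i >= 2, the number
    of edges among its neighbours divided by k_i(k_i-1)/2; nodes of degree
    < 2 contribute 0."""
    A = _check_adjacency(A)
    deg = A.sum(axis=1)
    # diagonal of A^3 counts closed triangles (twice per unordered pair)
    tri = np.diag(A @ A @ A) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return float(c.mean())


def characteristic_path_length(A: np.ndarray) -> float:
    """Mean shortest-path length over reachable ordered pairs (unweighted).

    Unreachable pairs are excluded from the average (the convention of the
    standard toolboxes); an edgeless graph has no defined L."""
    A = _check_adjacency(A)
    if A.sum() == 0:
        raise ValueError("characteristic path length undefined: no edges")
    D = shortest_path(A, method="D", unweighted=True)
    off = ~np.eye(A.shape[0], dtype=bool)
    finite = np.isfinite(D) & off
    return float(D[finite].mean())


def random_reference(A: np.ndarray, n_random: int = 10, seed: int = 0) -> list:
    """Degree-preserving randomized references (double-edge swaps).

    Graphs too small or rigid to rewire fall back to density-matched
    uniform random graphs with a warning."""
    A = _check_adjacency(A).astype(np.uint8)
    n = A.shape[0]
    m = int(A.sum() // 2)
    if m < 1:
        raise ValueError("need at least one edge to build references")
    G0 = nx.from_numpy_array(A)
    out = []
    rng = np.random.default_rng(seed)
    for i in range(n_random):
        G = G0.copy()
        try:
            if m < 2:
                raise nx.NetworkXException("too few edges to swap")
            nx.double_edge_swap(
                G,
                nswap=max(10 * m, 1),
                max_tries=max(1000 * m, 100),
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXException:
            warnings.warn(
                "degree-preserving rewiring infeasible; using a"
                " density-matched random graph"
            )
            G = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31 - 1)))
        out.append(nx.to_numpy_array(G, dtype=np.uint8))
    return out


@dataclass
class SmallWorldSummary:
    """Per-threshold raw and normalized metrics plus the across-threshold
    mean sigma.  Thresholds whose graphs were degenerate (no edges, or a
    zero random-reference clustering) are recorded in ``skipped``."""

    table: pd.DataFrame  # threshold, L, C, L_random, C_random, lambda, gamma, sigma
    mean_sigma: float
    skipped: list

    def __post_init__(self):
        t = self.table
        if len(t):
            assert np.allclose(t["sigma"], t["gamma"] / t["lambda"], atol=1e-12)


def small_world_summary(
    adjset: AdjacencySet,
    n_random: int = 10,
    seed: int = 0,
    reference_factory=None,
) -> SmallWorldSummary:
    """Normalized small-world metrics for every threshold of one scan.

    ``reference_factory(A, n_random, seed)`` may replace the default
    degree-preserving rewiring to supply the null ensemble."""
    factory = reference_factory or (
        lambda A, n, s: random_reference(A, n_random=n, seed=s)
    )
    rows, skipped = [], []
    for i, (tau, A) in enumerate(adjset):
        if A.sum() == 0:
            warnings.warn(f"threshold {tau}: empty graph, skipped")
            skipped.append(tau)
            continue
        L = characteristic_path_length(A)
        C = clustering_coefficient(A)
        refs = factory(A, n_random, seed + i)
        L_rand = float(np.mean([characteristic_path_length(R) for R in refs]))
        C_rand = float(np.mean([clustering_coefficient(R) for R in refs]))
        if C_rand == 0 or L_rand == 0:
            warnings.warn(
                f"threshold {tau}: random-reference C or L is zero;"
                " gamma/sigma undefined, skipped"
            )
            skipped.append(tau)
            continue
        lam = L / L_rand
        gam = C / C_rand
        rows.append(
            {
                "threshold": tau,
                "L": L,
                "C": C,
                "L_random": L_rand,
                "C_random": C_rand,
                "lambda": lam,
                "gamma": gam,
                "sigma": gam / lam,
            }
        )
    table = pd.DataFrame(rows)
    mean_sigma = float(table["sigma"].mean()) if len(table) else float("nan")
    return SmallWorldSummary(table=table, mean_sigma=mean_sigma, skipped=skipped)


def group_compare(
    values_a, values_b, paired: bool = False
) -> dict:
    """Two-group comparison formatted like the outcome tables:
    mean ± sd per group and a t-test p-value (paired within a group's
    before/after design, Welch across independent groups)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length groups")
        diffs = a - b
        if np.allclose(diffs, 0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_rel(a, b)
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "t": float(t_stat),
        "p_value": float(p),
        "paired": paired,
    }
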
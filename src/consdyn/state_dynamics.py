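"""Integrated/segregated brain-state decomposition of dynamic FC.

Each window matrix is profiled cartographically: signed-Louvain modules,
then the joint histogram of node participation coefficients and
within-module z-scores.  Windows are clustered (k-means, k=2, correlation
distance, many restarts) on these histograms; the cluster with the higher
mean participation coefficient is the integrated state.  Per-state
centroid matrices are elementwise medians of the member windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import DynamicFCSeries, FCMatrix
from .graph_metrics import louvain_signed, node_cartography

INTEGRATED = "integrated"
SEGREGATED = "segregated"


@dataclass
class CartographicProfile:
    histograms: np.ndarray  # W x (B_p * B_z), rows sum to 1
    bins_p: np.ndarray
    bins_z: np.ndarray
    mean_pc_per_window: np.ndarray


@dataclass
class StateAssignment:
    labels: list[str]
    centroid_integrated: FCMatrix
    centroid_segregated: FCMatrix
    fraction_integrated: float
    kmeans_inertia: float
    n_restarts: int
    seed: int


def joint_pz_histogram(
    participation: np.ndarray,
    z_scores: np.ndarray,
    bins_p: np.ndarray,
    bins_z: np.ndarray,
) -> np.ndarray:
    """Row-normalised flattened joint histogram of (P_i, z_i) pairs.

    z values outside the z range are clipped into the outer bins.
    """
    p = np.clip(participation, bins_p[0], bins_p[-1])
    z = np.clip(z_scores, bins_z[0], bins_z[-1])
    h, _, _ = np.histogram2d(p, z, bins=[bins_p, bins_z])
    h = h.ravel()
    return h / h.sum()


def cartographic_profiles(
    dfc: DynamicFCSeries,
    gamma: float = 1.0,
    n_repeats: int = 100,
    seed: int = 0,
    n_bins_p: int = 10,
    n_bins_z: int = 10,
) -> CartographicProfile:
    """Per-window modularity -> cartography -> joint P/z histogram."""
    w = dfc.n_windows
    if w < 2:
        raise ValueError("need at least 2 windows")
    bins_p = np.linspace(0.0, 1.0, n_bins_p + 1)
    bins_z = np.linspace(-5.0, 5.0, n_bins_z + 1)
    rng = np.random.default_rng(seed)
    hists = np.zeros((w, n_bins_p * n_bins_z))
    mean_pc = np.zeros(w)
    for t, mat in enumerate(dfc.matrices):
        part = louvain_signed(mat, gamma=gamma, n_repeats=n_repeats, seed=rng)
        carto = node_cartography(mat, part)
        hists[t] = joint_pz_histogram(carto.participation, carto.within_module_z, bins_p, bins_z)
        mean_pc[t] = carto.participation.mean()
    return CartographicProfile(
        histograms=hists, bins_p=bins_p, bins_z=bins_z, mean_pc_per_window=mean_pc
    )


# ---------------------------------------------------------------------------
# k-means with correlation distance

def _corr_distance(rows: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """1 - Pearson r between each row and each centroid."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    cc = centroids - centroids.mean(axis=1, keepdims=True)
    rn = np.linalg.norm(rc, axis=1, keepdims=True)
    cn = np.linalg.norm(cc, axis=1, keepdims=True)
    rn[rn == 0] = 1.0
    cn[cn == 0] = 1.0
    return 1.0 - (rc / rn) @ (cc / cn).T


def _kmeans_correlation_once(
    rows: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    w = rows.shape[0]
    centroids = rows[rng.choice(w, size=k, replace=False)].copy()
    labels = np.full(w, -1)
    for _ in range(max_iter):
        d = _corr_distance(rows, centroids)
        new_labels = d.argmin(axis=1)
        for c in range(k):  # reseed empty clusters at the worst-fit point
            if not np.any(new_labels == c):
                far = d[np.arange(w), new_labels].argmax()
                centroids[c] = rows[far]
                new_labels[far] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = rows[labels == c].mean(axis=0)
    inertia = float(_corr_distance(rows, centroids)[np.arange(w), labels].sum())
    return labels, inertia


def kmeans_states(
    profile: CartographicProfile,
    k: int = 2,
    n_restarts: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Best-of-restarts k-means on histogram rows with correlation distance.

    Returns binary cluster indices (0/1) and the winning total
    within-cluster distance.  Raises on degenerate input where every row is
    identical (correlation distance cannot separate anything).
    """
    rows = profile.histograms
    w = rows.shape[0]
    if w < k:
        raise ValueError("fewer windows than clusters")
    if np.allclose(rows, rows[0]):
        raise ValueError("degenerate input: all histogram rows identical")
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _ in range(n_restarts):
        labels, inertia = _kmeans_correlation_once(rows, k, rng)
        if inertia < best_inertia - 1e-15:
            best_labels, best_inertia = labels, inertia
    return best_labels, best_inertia


def label_states(cluster_idx: np.ndarray, mean_pc_per_window: np.ndarray) -> list[str]:
    """Name the cluster with higher mean participation 'integrated'."""
    pc0 = mean_pc_per_window[cluster_idx == 0].mean()
    pc1 = mean_pc_per_window[cluster_idx == 1].mean()
    integrated_cluster = 0 if pc0 >= pc1 else 1
    return [INTEGRATED if c == integrated_cluster else SEGREGATED for c in cluster_idx]


def state_centroids(dfc: DynamicFCSeries, labels: list[str]) -> tuple[FCMatrix, FCMatrix]:
    """Elementwise median FC matrix per state."""
    stack = dfc.stacked()
    lab = np.asarray(labels)
    out = []
    for state, prov in ((INTEGRATED, "centroid_integrated"), (SEGREGATED, "centroid_segregated")):
        members = stack[lab == state]
        if members.shape[0] == 0:
            raise ValueError(f"empty state {state!r}")
        med = np.median(members, axis=0)
        med = (med + med.T) / 2.0
        out.append(FCMatrix(weights=med, region_ids=list(dfc.matrices[0].region_ids), provenance=prov))
    return out[0], out[1]


def time_in_state(labels: list[str]) -> tuple[float, float]:
    """Occupancy fractions (integrated, segregated); they sum to 1."""
    if len(labels) == 0:
        raise ValueError("no windows")
    n_int = sum(1 for l in labels if l == INTEGRATED)
    f = n_int / len(labels)
    return f, 1.0 - f


def derive_states(
    dfc: DynamicFCSeries,
    gamma: float = 1.0,
    louvain_repeats: int = 100,
    kmeans_restarts: int = 500,
    seed: int = 0,
) -> StateAssignment:
    """Full chain: cartographic profiles -> k-means -> labelled states."""
    profile = cartographic_profiles(dfc, gamma=gamma, n_repeats=louvain_repeats, seed=seed)
    cluster_idx, inertia = kmeans_states(profile, k=2, n_restarts=kmeans_restarts, seed=seed + 1)
    labels = label_states(cluster_idx, profile.mean_pc_per_window)
    cen_int, cen_seg = state_centroids(dfc, labels)
    f_int, _ = time_in_state(labels)
    return StateAssignment(
        labels=labels,
        centroid_integrated=cen_int,
        centroid_segregated=cen_seg,
        fraction_integrated=f_int,
        kmeans_inertia=inertia,
        n_restarts=kmeans_restarts,
        seed=seed,
    )
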
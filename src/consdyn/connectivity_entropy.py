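"""Connectivity entropy: normalised Shannon entropy of each node's FC
value distribution.

Each node's N-1 off-diagonal connectivity values are binned into n
equal-width bins over [-1, 1]; the Shannon entropy of the bin proportions,
divided by log(n), gives a diversity index in [0, 1]: 0 when all values
fall in one bin, 1 when the bins are filled in exactly equal proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import FCMatrix

YEO7_NETWORKS = ("DMN", "SOM", "VIS", "SAL", "DAN", "FPN", "LIM")


@dataclass
class NetworkLabels:
    """Per-node resting-state network assignment (7-network scheme)."""

    assignment: list[str]

    def __post_init__(self) -> None:
        unknown = set(self.assignment) - set(YEO7_NETWORKS)
        if unknown:
            raise ValueError(f"unknown network label(s): {sorted(unknown)}")


@dataclass
class ConnectivityEntropyResult:
    node_entropy: np.ndarray
    bin_probabilities: np.ndarray
    n_bins: int
    global_mean: float
    network_means: dict[str, float] = field(default_factory=dict)


def connectivity_entropy_nodes(
    fc: FCMatrix | np.ndarray,
    n_bins: int = 10,
    value_range: tuple[float, float] = (-1.0, 1.0),
) -> ConnectivityEntropyResult:
    """Node-wise H = -sum_i p_i log(p_i) / log(n) over binned FC values.

    The diagonal (self-correlation) is excluded from each node's
    distribution.  Values are clipped into the bin range; 0*log(0) := 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    w = fc.weights if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    n = w.shape[0]
    edges = np.linspace(value_range[0], value_range[1], n_bins + 1)
    probs = np.zeros((n, n_bins))
    h = np.zeros(n)
    for i in range(n):
        vals = np.delete(w[:, i], i)
        vals = np.clip(vals, value_range[0], value_range[1])
        counts, _ = np.histogram(vals, bins=edges)
        p = counts / counts.sum()
        probs[i] = p
        nz = p > 0
        h[i] = float(-(p[nz] * np.log(p[nz])).sum() / np.log(n_bins))
    return ConnectivityEntropyResult(
        node_entropy=h,
        bin_probabilities=probs,
        n_bins=n_bins,
        global_mean=float(h.mean()),
    )


def summarize_by_network(
    res: ConnectivityEntropyResult, labels: NetworkLabels
) -> dict[str, float]:
    """Unweighted mean node entropy within each network label."""
    if len(labels.assignment) != res.node_entropy.size:
        raise ValueError("labels do not cover all nodes")
    out: dict[str, float] = {}
    lab = np.asarray(labels.assignment)
    for net in sorted(set(labels.assignment)):
        out[net] = float(res.node_entropy[lab == net].mean())
    res.network_means = out
    return out
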
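"""Graph-theoretical metrics on thresholded brain networks.

Implements signed modularity maximisation (Louvain with the asymmetric
positive/negative objective), cartographic node measures (participation
coefficient, within-module degree z-score), weighted characteristic path
length and clustering, proportional thresholding, degree-preserving
rewiring nulls and small-worldness.

The signed modularity being maximised is

    Q = (1/v+) sum_ij (w+_ij - e+_ij) d_ij  -  (1/(v+ + v-)) sum_ij (w-_ij - e-_ij) d_ij

with w+/w- the positive/negative parts of the weight matrix, v+/v- their
total weights, chance terms e±_ij = s±_i s±_j / v± (strength-product null)
and d_ij = 1 when nodes i and j share a module.  Positive within-module
weight is rewarded at full strength while negative within-module weight is
penalised at reduced strength — the asymmetric convention for signed
functional-connectivity networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import FCMatrix


@dataclass
class ModulePartition:
    assignment: np.ndarray  # module of node i, labels 1..M
    n_modules: int
    q_value: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        labels = np.unique(self.assignment)
        if not np.array_equal(labels, np.arange(1, labels.size + 1)):
            raise ValueError("modules must be labelled 1..M contiguously")
        if self.n_modules != labels.size:
            raise ValueError("n_modules inconsistent with assignment")


@dataclass
class ModularityContext:
    total_positive_weight: float
    total_negative_weight: float
    chance_expected_pos: np.ndarray
    chance_expected_neg: np.ndarray


@dataclass
class NodeCartography:
    participation: np.ndarray
    module_strengths: np.ndarray  # N x M positive strength into each module
    total_positive_strength: np.ndarray
    within_module_z: np.ndarray
    module_mean_strength: np.ndarray
    module_sd_strength: np.ndarray


@dataclass
class BrainGraph:
    weights: np.ndarray
    density: float
    binarized: bool = False

    def __post_init__(self) -> None:
        # negative weights can survive thresholding only at extreme densities;
        # the metric operations below require nonnegative weights
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self-loops not allowed")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int((np.triu(self.weights, 1) > 0).sum())


@dataclass
class GraphMetrics:
    char_path_length: float = math.nan
    distance_matrix: np.ndarray | None = None
    n_nodes: int = 0
    n_unreachable_pairs: int = 0
    clustering: np.ndarray | None = None
    triangle_intensity: np.ndarray | None = None
    degree: np.ndarray | None = None


@dataclass
class SmallWorldResult:
    s_value: float
    c_graph: float
    c_random: float
    l_graph: float
    l_random: float
    n_nulls: int
    per_density: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# thresholding

def proportional_threshold(fc: FCMatrix | np.ndarray, density: float, binarize: bool = False) -> BrainGraph:
    """Keep the top ``density`` fraction of edges by signed weight.

    Edges are ranked by signed value (strong anticorrelations drop out at
    low densities); ties broken by (i, j) lexicographic order.  Retained
    weights are kept (or set to 1 when ``binarize``); everything else,
    including the diagonal, is zeroed.
    """
    w = fc.weights if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    n = w.shape[0]
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    n_edges_total = vals.size
    k = int(math.ceil(density * n_edges_total))
    if k < 1:
        raise ValueError("density retains fewer than 1 edge")
    order = np.lexsort((ju, iu, -vals))  # by descending weight, then (i, j)
    keep = order[:k]
    out = np.zeros_like(w)
    kept_vals = np.ones(k) if binarize else vals[keep]
    out[iu[keep], ju[keep]] = kept_vals
    out[ju[keep], iu[keep]] = kept_vals
    return BrainGraph(weights=out, density=k / n_edges_total, binarized=binarize)


# ---------------------------------------------------------------------------
# signed modularity

def _split_signed(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w = np.asarray(w, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    return np.clip(w, 0, None), np.clip(-w, 0, None)


def modularity_context(w: np.ndarray, gamma: float = 1.0) -> ModularityContext:
    wp, wn = _split_signed(w)
    vp, vn = wp.sum(), wn.sum()
    sp, sn = wp.sum(axis=1), wn.sum(axis=1)
    ep = gamma * np.outer(sp, sp) / vp if vp > 0 else np.zeros_like(wp)
    en = gamma * np.outer(sn, sn) / vn if vn > 0 else np.zeros_like(wn)
    return ModularityContext(vp, vn, ep, en)


def _modularity_b_matrix(w: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Generalised signed modularity matrix; Q(c) = sum_ij B_ij d(c_i, c_j)."""
    ctx = modularity_context(w, gamma)
    wp, wn = _split_signed(w)
    b = np.zeros_like(wp)
    if ctx.total_positive_weight > 0:
        b += (wp - ctx.chance_expected_pos) / ctx.total_positive_weight
    denom = ctx.total_positive_weight + ctx.total_negative_weight
    if ctx.total_negative_weight > 0:
        b -= (wn - ctx.chance_expected_neg) / denom
    return (b + b.T) / 2.0


def modularity_signed(fc: FCMatrix | np.ndarray, assignment: np.ndarray, gamma: float = 1.0) -> float:
    """Evaluate signed Q for a given module assignment."""
    w = fc.weights if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    b = _modularity_b_matrix(w, gamma)
    a = np.asarray(assignment)
    same = a[:, None] == a[None, :]
    return float(b[same].sum())


def _relabel_contiguous(assignment: np.ndarray) -> np.ndarray:
    out = np.empty_like(assignment)
    seen: dict[int, int] = {}
    for i, c in enumerate(assignment):
        if c not in seen:
            seen[c] = len(seen) + 1
        out[i] = seen[c]
    return out


def _louvain_once(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Louvain run on a generalised modularity matrix (dense)."""
    n0 = b.shape[0]
    node_comm = np.arange(n0)  # community of each original node
    bc = b.copy()
    groups = [[i] for i in range(n0)]  # original nodes per current super-node

    while True:
        n = bc.shape[0]
        comm = np.arange(n)
        improved = False
        moved = True
        while moved:
            moved = False
            for i in rng.permutation(n):
                ci = comm[i]
                row = bc[i].copy()
                row[i] = 0.0
                gains = np.zeros(comm.max() + 1)
                np.add.at(gains, comm, row)
                gains_rel = gains - gains[ci]
                best = int(np.argmax(gains_rel))
                if gains_rel[best] > 1e-12 and best != ci:
                    comm[i] = best
                    moved = True
                    improved = True
        if not improved:
            break
        # aggregate
        labels, inv = np.unique(comm, return_inverse=True)
        m = labels.size
        if m == n:
            break
        agg = np.zeros((m, m))
        for a in range(m):
            sel_a = inv == a
            agg[a] = bc[sel_a].sum(axis=0) @ _onehot(inv, m)
        bc = agg
        new_groups: list[list[int]] = [[] for _ in range(m)]
        for old, new in enumerate(inv):
            new_groups[new].extend(groups[old])
        groups = new_groups

    assignment = np.empty(n0, dtype=int)
    for c, members in enumerate(groups):
        assignment[members] = c
    return _relabel_contiguous(assignment)


def _onehot(labels: np.ndarray, m: int) -> np.ndarray:
    out = np.zeros((labels.size, m))
    out[np.arange(labels.size), labels] = 1.0
    return out


def louvain_signed(
    fc: FCMatrix | np.ndarray,
    gamma: float = 1.0,
    n_repeats: int = 100,
    seed: int | np.random.Generator = 0,
) -> ModulePartition:
    """Best-of-``n_repeats`` Louvain maximisation of signed modularity.

    Each repeat uses a distinct RNG stream; the partition with the highest
    Q is returned with Q recomputed directly from the assignment.  Ties go
    to the earliest repeat.
    """
    w = fc.weights if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    wz = w.copy()
    np.fill_diagonal(wz, 0.0)
    if not np.any(wz):
        raise ValueError("all-zero matrix has no module structure")
    b = _modularity_b_matrix(w, gamma)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best_q, best_assign = -np.inf, None
    for _ in range(n_repeats):
        assignment = _louvain_once(b, rng)
        same = assignment[:, None] == assignment[None, :]
        q = float(b[same].sum())
        if q > best_q + 1e-15:
            best_q, best_assign = q, assignment
    q_final = modularity_signed(w, best_assign, gamma)
    return ModulePartition(
        assignment=best_assign,
        n_modules=int(best_assign.max()),
        q_value=q_final,
        gamma=gamma,
    )


# ---------------------------------------------------------------------------
# cartography

def node_cartography(fc: FCMatrix | np.ndarray, part: ModulePartition) -> NodeCartography:
    """Participation coefficient and within-module z-score (positive weights).

    P_i = 1 - sum_s (k_is / k_i)^2 over the node's positive strength into
    each module; nodes with zero positive strength get P_i = 0.  z_i
    standardises the node's positive strength into its own module by that
    module's member mean and SD; sigma = 0 modules give z_i = 0.
    """
    w = fc.weights if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    wp = np.clip(w, 0, None).copy()
    np.fill_diagonal(wp, 0.0)
    a = part.assignment
    n = w.shape[0]
    m = part.n_modules
    if a.size != n:
        raise ValueError("partition does not cover all nodes")
    onehot = np.zeros((n, m))
    onehot[np.arange(n), a - 1] = 1.0
    kappa = wp @ onehot  # N x M positive strength into each module
    k = kappa.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(k[:, None] > 0, kappa / k[:, None], 0.0)
    participation = np.where(k > 0, 1.0 - (frac**2).sum(axis=1), 0.0)

    own = kappa[np.arange(n), a - 1]
    mod_mean = np.zeros(m)
    mod_sd = np.zeros(m)
    z = np.zeros(n)
    for s in range(1, m + 1):
        members = a == s
        if not members.any():
            raise ValueError(f"empty module {s}")
        vals = own[members]
        mod_mean[s - 1] = vals.mean()
        mod_sd[s - 1] = vals.std(ddof=0)
        if mod_sd[s - 1] > 0:
            z[members] = (vals - mod_mean[s - 1]) / mod_sd[s - 1]
    return NodeCartography(
        participation=participation,
        module_strengths=kappa,
        total_positive_strength=k,
        within_module_z=z,
        module_mean_strength=mod_mean,
        module_sd_strength=mod_sd,
    )


# ---------------------------------------------------------------------------
# path length / clustering

def weighted_path_length(g: BrainGraph) -> GraphMetrics:
    """Characteristic path length with edge lengths 1/weight.

    Unreachable pairs are excluded from the average; their count is
    reported in ``n_unreachable_pairs``.
    """
    w = g.weights
    if np.any(w < 0):
        raise ValueError("path length requires nonnegative weights")
    if not np.any(w):
        raise ValueError("graph has no edges")
    n = w.shape[0]
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 if g.binarized else 1.0 / w[nz]
    d = shortest_path(csr_matrix(lengths), method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_unreachable = int((off & ~finite).sum())
    cpl = float(d[finite].mean()) if finite.any() else math.nan
    return GraphMetrics(
        char_path_length=cpl,
        distance_matrix=d,
        n_nodes=n,
        n_unreachable_pairs=n_unreachable,
    )


def weighted_clustering(g: BrainGraph) -> GraphMetrics:
    """Weighted clustering C_i = 2 t_i / (k_i (k_i - 1)).

    t_i is the geometric-mean triangle intensity around node i with weights
    scaled by the maximum weight; k_i is the binary degree; C_i = 0 when
    k_i < 2.
    """
    w = g.weights
    if np.any(w < 0):
        raise ValueError("clustering requires nonnegative weights")
    if not np.any(w):
        raise ValueError("graph has no edges")
    wmax = w.max()
    what = w / wmax
    cube = np.cbrt(what)
    t = np.diag(cube @ cube @ cube) / 2.0
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, 2.0 * t / denom, 0.0)
    return GraphMetrics(
        clustering=c,
        triangle_intensity=t,
        degree=k.astype(int),
        n_nodes=w.shape[0],
    )


# ---------------------------------------------------------------------------
# null models

def rewire_null(
    g: BrainGraph,
    swaps_per_edge: int = 100,
    seed: int | np.random.Generator = 0,
) -> BrainGraph:
    """Degree-preserving double-edge-swap null; weights travel with edges.

    Attempts ``swaps_per_edge * n_edges`` swaps of edge pairs (a,b),(c,d)
    -> (a,d),(c,b), rejecting proposals that would create self-loops or
    multi-edges.  The binary degree sequence and the multiset of edge
    weights are exactly preserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(g.weights, 1))
    n_edges = iu.size
    if n_edges < 2:
        raise ValueError("graph too small to rewire")
    edges = [[int(a), int(b)] for a, b in zip(iu, ju)]
    wts = [g.weights[a, b] for a, b in zip(iu, ju)]
    present = {(a, b) for a, b in edges}
    n_attempts = swaps_per_edge * n_edges
    pick = rng.integers(0, n_edges, size=(n_attempts, 2))
    flip = rng.integers(0, 2, size=(n_attempts, 2))
    for t in range(n_attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip[t, 0]:
            a, b = b, a
        if flip[t, 1]:
            c, d = d, c
        # propose (a,d) and (c,b)
        if a == d or c == b:
            continue
        n1 = (min(a, d), max(a, d))
        n2 = (min(c, b), max(c, b))
        if n1 in present or n2 in present or n1 == n2:
            continue
        present.discard((min(a, b), max(a, b)))
        present.discard((min(c, d), max(c, d)))
        present.add(n1)
        present.add(n2)
        edges[e1] = [n1[0], n1[1]]
        edges[e2] = [n2[0], n2[1]]
    out = np.zeros_like(g.weights)
    for (a, b), wv in zip(edges, wts):
        out[a, b] = wv
        out[b, a] = wv
    return BrainGraph(weights=out, density=g.density, binarized=g.binarized)


def small_worldness(
    fc: FCMatrix | np.ndarray,
    densities: list[float] = (0.10, 0.15, 0.20, 0.25),
    n_nulls: int = 100,
    binarize: bool = False,
    seed: int | np.random.Generator = 0,
    swaps_per_edge: int = 100,
) -> SmallWorldResult:
    """Small-worldness S = (C/C_rand) / (L/L_rand), averaged over densities.

    At each density the matrix is proportionally thresholded, mean
    clustering C and characteristic path length L are computed, and each is
    normalised by the mean over ``n_nulls`` degree-preserving rewired
    graphs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_density = {}
    s_values, cs, crs, ls, lrs = [], [], [], [], []
    for dens in densities:
        g = proportional_threshold(fc, dens, binarize=binarize)
        pm = weighted_path_length(g)
        cm = weighted_clustering(g)
        c_graph = float(np.mean(cm.clustering))
        l_graph = pm.char_path_length
        c_nulls, l_nulls = [], []
        for _ in range(n_nulls):
            gr = rewire_null(g, swaps_per_edge=swaps_per_edge, seed=rng)
            c_nulls.append(float(np.mean(weighted_clustering(gr).clustering)))
            l_nulls.append(weighted_path_length(gr).char_path_length)
        c_rand = float(np.mean(c_nulls))
        l_rand = float(np.mean(l_nulls))
        s = (c_graph / c_rand) / (l_graph / l_rand)
        per_density[dens] = {
            "s": s, "c": c_graph, "c_random": c_rand, "l": l_graph, "l_random": l_rand,
        }
        s_values.append(s)
        cs.append(c_graph)
        crs.append(c_rand)
        ls.append(l_graph)
        lrs.append(l_rand)
    return SmallWorldResult(
        s_value=float(np.mean(s_values)),
        c_graph=float(np.mean(cs)),
        c_random=float(np.mean(crs)),
        l_graph=float(np.mean(ls)),
        l_random=float(np.mean(lrs)),
        n_nulls=n_nulls,
        per_density=per_density,
    )
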
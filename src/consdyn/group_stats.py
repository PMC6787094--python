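"""Group statistics: permutation t-tests, Hedges' g, Benjamini-Hochberg
FDR, edgewise connectivity contrasts, and the cross-dataset
common-difference combination rule.

Permutation tests are two-sided.  Paired designs use sign-flipping of the
within-subject differences; unpaired designs shuffle group labels around a
pooled-variance t statistic.  Monte-Carlo p-values use the add-one
convention (1 + #{|t*| >= |t|}) / (n_perm + 1); when every distinct
permutation can be enumerated the test switches to exact enumeration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .connectivity import FCMatrix


@dataclass
class StatResult:
    t_observed: float
    p_value: float
    effect_g: float
    n_permutations: int
    paired: bool
    seed: int
    exhaustive: bool = False


@dataclass
class CommonDiffMatrix:
    """Edges consistently altered (same sign, conservative magnitude) in two
    thresholded contrast matrices."""

    weights: np.ndarray
    provenance_a: str = ""
    provenance_b: str = ""

    @property
    def n_nonzero_edges(self) -> int:
        return int((np.triu(self.weights, 1) != 0).sum())


# ---------------------------------------------------------------------------
# core statistics

def _t_paired(d: np.ndarray) -> float:
    n = d.size
    sd = d.std(ddof=1)
    m = d.mean()
    if sd == 0:
        return 0.0 if m == 0 else math.copysign(math.inf, m)
    return m / (sd / math.sqrt(n))


def _t_pooled(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    diff = x.mean() - y.mean()
    if sp2 == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))


def _paired_t_vector(signs: np.ndarray, d: np.ndarray) -> np.ndarray:
    """t statistics for many sign-flip patterns at once (rows of ``signs``)."""
    n = d.size
    m = (signs * d).mean(axis=1)
    ssq = float((d**2).sum())
    var = (ssq - n * m**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    t[np.isnan(t)] = 0.0  # 0/0: all-zero differences
    return t


def permutation_ttest(
    x: np.ndarray,
    y: np.ndarray,
    paired: bool = False,
    n_perm: int = 10000,
    seed: int = 0,
) -> StatResult:
    """Two-sided permutation t-test (sign-flip if paired, label-shuffle if not)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        if x.size < 2:
            raise ValueError("need at least 2 pairs")
        d = x - y
        t_obs = _t_paired(d)
        n = d.size
        exhaustive = 2**n <= n_perm
        if exhaustive:
            signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
        else:
            signs = rng.choice([1.0, -1.0], size=(n_perm, n))
        t_null = _paired_t_vector(signs, d)
        p = _two_sided_p(t_null, t_obs, exhaustive)
        g = hedges_g(x, y, paired=True)
        return StatResult(t_obs, p, g, signs.shape[0], True, seed, exhaustive)

    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    t_obs = _t_pooled(x, y)
    pooled = np.concatenate([x, y])
    n1, n_tot = x.size, x.size + y.size
    n_distinct = math.comb(n_tot, n1)
    exhaustive = n_distinct <= n_perm
    if exhaustive:
        t_null = np.array(
            [
                _t_pooled(pooled[list(idx)], np.delete(pooled, list(idx)))
                for idx in itertools.combinations(range(n_tot), n1)
            ]
        )
    else:
        t_null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(n_tot)
            t_null[i] = _t_pooled(pooled[perm[:n1]], pooled[perm[n1:]])
    p = _two_sided_p(t_null, t_obs, exhaustive)
    g = hedges_g(x, y, paired=False)
    return StatResult(t_obs, p, g, t_null.size, False, seed, exhaustive)


def _two_sided_p(t_null: np.ndarray, t_obs: float, exhaustive: bool) -> float:
    hits = int((np.abs(t_null) >= abs(t_obs) - 1e-12).sum())
    if exhaustive:  # identity permutation is in the enumeration: exact p
        return hits / t_null.size
    return (1 + hits) / (t_null.size + 1)


def hedges_g(x: np.ndarray, y: np.ndarray, paired: bool = False) -> float:
    """Bias-corrected standardised mean difference.

    Paired: mean of differences over the SD of differences, df = n - 1.
    Two-sample: pooled-SD standardisation, df = n1 + n2 - 2.  The
    small-sample correction is J = 1 - 3/(4 df - 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        d = x - y
        sd = d.std(ddof=1)
        if sd == 0:
            if d.mean() == 0:
                return 0.0
            raise ValueError("zero SD of differences with nonzero mean")
        df = d.size - 1
        return float(d.mean() / sd * (1 - 3 / (4 * df - 1)))
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        if x.mean() == y.mean():
            return 0.0
        raise ValueError("zero pooled SD with unequal means")
    df = n1 + n2 - 2
    return float((x.mean() - y.mean()) / math.sqrt(sp2) * (1 - 3 / (4 * df - 1)))


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control; returns (q_values, reject)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


# ---------------------------------------------------------------------------
# edgewise contrasts

def _edge_vectors(stack: list[FCMatrix]) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    n = stack[0].n_regions
    iu, ju = np.triu_indices(n, k=1)
    mats = np.stack([m.weights for m in stack])
    return mats[:, iu, ju], iu, ju, n


def edgewise_contrast(
    fc_stack_a: list[FCMatrix],
    fc_stack_b: list[FCMatrix],
    paired: bool = False,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
) -> FCMatrix:
    """Mean-difference matrix (A - B) thresholded by edgewise permutation
    tests with BH-FDR over the N(N-1)/2 unique edges."""
    if not fc_stack_a or not fc_stack_b:
        raise ValueError("empty FC stack")
    if fc_stack_a[0].n_regions != fc_stack_b[0].n_regions:
        raise ValueError("dimension mismatch between stacks")
    xa, iu, ju, n = _edge_vectors(fc_stack_a)
    xb, _, _, _ = _edge_vectors(fc_stack_b)
    rng = np.random.default_rng(seed)

    if paired:
        if xa.shape[0] != xb.shape[0]:
            raise ValueError("paired stacks must have equal length")
        d = xa - xb  # n_subj x E
        ns = d.shape[0]
        t_obs = _t_matrix_paired(np.ones((1, ns)), d)[0]
        exhaustive = 2**ns <= n_perm
        signs = (
            np.array(list(itertools.product([1.0, -1.0], repeat=ns)))
            if exhaustive
            else rng.choice([1.0, -1.0], size=(n_perm, ns))
        )
        t_null = _t_matrix_paired(signs, d)
        p = _p_matrix(t_null, t_obs, exhaustive)
        mean_diff = d.mean(axis=0)
    else:
        n1, n2 = xa.shape[0], xb.shape[0]
        x = np.vstack([xa, xb])
        t_obs = _t_matrix_pooled(x, np.arange(n1), n1, n2)
        exhaustive = math.comb(n1 + n2, n1) <= n_perm
        if exhaustive:
            combos = list(itertools.combinations(range(n1 + n2), n1))
            t_null = np.stack([_t_matrix_pooled(x, np.array(c), n1, n2) for c in combos])
        else:
            t_null = np.empty((n_perm, t_obs.size))
            for i in range(n_perm):
                perm = rng.permutation(n1 + n2)
                t_null[i] = _t_matrix_pooled(x, perm[:n1], n1, n2)
        p = _p_matrix(t_null, t_obs, exhaustive)
        mean_diff = xa.mean(axis=0) - xb.mean(axis=0)

    _, reject = bh_fdr(p, alpha=alpha)
    out = np.zeros((n, n))
    kept = mean_diff * reject
    out[iu, ju] = kept
    out[ju, iu] = kept
    return FCMatrix(
        weights=out, region_ids=list(fc_stack_a[0].region_ids), provenance="mean_difference"
    )


def _t_matrix_paired(signs: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Paired t per edge for each sign-flip row; result (n_perm x E)."""
    ns = d.shape[0]
    m = signs @ d / ns
    ssq = (d**2).sum(axis=0)
    var = np.maximum((ssq[None, :] - ns * m**2) / (ns - 1), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / ns)
    t[np.isnan(t)] = 0.0
    return t


def _t_matrix_pooled(x: np.ndarray, idx_a: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Pooled two-sample t per edge for one assignment of rows to group A."""
    mask = np.zeros(x.shape[0], dtype=bool)
    mask[idx_a] = True
    xa, xb = x[mask], x[~mask]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    ssa = ((xa - ma) ** 2).sum(axis=0)
    ssb = ((xb - mb) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t[np.isnan(t)] = 0.0
    return t


def _p_matrix(t_null: np.ndarray, t_obs: np.ndarray, exhaustive: bool) -> np.ndarray:
    hits = (np.abs(t_null) >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
    if exhaustive:
        return hits / t_null.shape[0]
    return (1 + hits) / (t_null.shape[0] + 1)


def combine_common_differences(mat_a: FCMatrix, mat_b: FCMatrix) -> CommonDiffMatrix:
    """Conservative intersection of two thresholded contrast matrices.

    If both matrices have a positive edge at (i, j), the output takes the
    minimum of the two; if both are negative, the maximum (smaller absolute
    value); otherwise 0.  A nonzero output edge therefore marks a
    consistent alteration, with the conservative magnitude.
    """
    a, b = mat_a.weights, mat_b.weights
    if a.shape != b.shape:
        raise ValueError("dimension mismatch")
    out = np.zeros_like(a)
    both_pos = (a > 0) & (b > 0)
    both_neg = (a < 0) & (b < 0)
    out[both_pos] = np.minimum(a, b)[both_pos]
    out[both_neg] = np.maximum(a, b)[both_neg]
    return CommonDiffMatrix(
        weights=out, provenance_a=mat_a.provenance, provenance_b=mat_b.provenance
    )
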
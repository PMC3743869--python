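"""Mantel and CADM congruence tests between distance matrices.

The Mantel test measures association between two distance matrices via the
cross-product statistic Z = sum_{i<j} d1_ij * d2_ij, with significance from
simultaneous row/column permutations of one matrix.  Reported alongside Z
are the standardized Mantel correlation r (Pearson correlation of the
unrolled upper triangles) and a standardized deviate
t = (Z - mean(Z_null)) / sd(Z_null).

CADM (congruence among distance matrices) ranks each matrix's unrolled
distances (mid-ranks for ties) and measures concordance with Kendall's W,
tie-corrected:

    W = 12 S / (m^2 (N^3 - N) - m T)

where S is the sum over items of squared deviations of rank sums from
their mean and T the tie correction summed over matrices.  The global null
permutes the objects of every matrix independently; the a posteriori
statistic of matrix k is the Pearson correlation between its ranks and the
mean ranks of the other matrices, tested by permuting matrix k only.  For
m = 2 the identity W = (1 + rho)/2 links W to the rank correlation.

Permutation p-values use the (1 + count) / (1 + n_perm) convention; the
minimum attainable p is 1/(n_perm + 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrices import DistanceMatrix, check_aligned

__all__ = [
    "MantelResult",
    "CADMResult",
    "unroll",
    "mantel_test",
    "kendall_w",
    "cadm_test",
    "congruence_report",
]


def unroll(d: DistanceMatrix) -> np.ndarray:
    """Row-major upper-triangle (i<j) vector; length n(n-1)/2."""
    return d.condensed()


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0 or sy == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(xc @ yc / (sx * sy))


@dataclass
class MantelResult:
    Z: float
    r: float
    t: float
    p: float
    n_perm: int
    seed: int | None
    tail: str = "greater"


def _null_permutations(n: int, n_perm, seed):
    """Yield object permutations: random with a seed, or all n! if exhaustive."""
    if n_perm == "exhaustive":
        yield from (np.array(p) for p in itertools.permutations(range(n)))
    else:
        n_perm = int(n_perm)
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            yield rng.permutation(n)


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int | str = 1000,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Mantel permutation test between two label-aligned distance matrices.

    ``n_perm`` may be "exhaustive" to enumerate all n! object permutations
    (exact test; identity included in the null).  ``tail`` is "greater",
    "less" or "two-sided".
    """
    check_aligned(d1, d2)
    n = d1.n
    if n < 4:
        raise ValueError("Mantel test needs at least 4 objects")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    v2 = d2.values[iu]
    for name, v in (("d1", v1), ("d2", v2)):
        if np.ptp(v) == 0:
            raise ValueError(f"matrix {name} is constant off-diagonal; r undefined")
    Z = float(v1 @ v2)
    r = _pearson(v1, v2)

    null = np.array([
        float(v1 @ d2.values[np.ix_(p, p)][iu]) for p in _null_permutations(n, n_perm, seed)
    ])
    mu, sd = float(null.mean()), float(null.std(ddof=0))
    t = (Z - mu) / sd if sd > 0 else math.nan
    if n_perm == "exhaustive":
        total = len(null)
        if tail == "greater":
            p = float(np.sum(null >= Z) / total)
        elif tail == "less":
            p = float(np.sum(null <= Z) / total)
        else:
            p = float(np.sum(np.abs(null - mu) >= abs(Z - mu)) / total)
        n_used = total
    else:
        n_used = len(null)
        if tail == "greater":
            c = int(np.sum(null >= Z))
        elif tail == "less":
            c = int(np.sum(null <= Z))
        else:
            c = int(np.sum(np.abs(null - mu) >= abs(Z - mu)))
        p = (1 + c) / (n_used + 1)
    return MantelResult(Z=Z, r=r, t=t, p=p, n_perm=n_used, seed=seed, tail=tail)


# ----------------------------------------------------------------------
# Kendall's W and CADM
# ----------------------------------------------------------------------

def _tie_correction(row: np.ndarray) -> float:
    """Sum of (t^3 - t) over groups of tied mid-ranks in one rank row."""
    _vals, counts = np.unique(row, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kendall_w(rank_rows: np.ndarray) -> float:
    """Tie-corrected Kendall coefficient of concordance of m rank rows."""
    R = np.asarray(rank_rows, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("need m >= 2 rank rows")
    m, N = R.shape
    for k in range(m):
        if np.ptp(R[k]) == 0:
            raise ValueError(f"rank row {k} is constant; W undefined")
    T = sum(_tie_correction(R[k]) for k in range(m))
    sums = R.sum(axis=0)
    S = float(np.sum((sums - sums.mean()) ** 2))
    denom = m * m * (N**3 - N) - m * T
    return 12.0 * S / denom


@dataclass
class CADMResult:
    W: float
    p_global: float
    posthoc: list[tuple[float, float]]  # per matrix: (mantel correlation on ranks, p)
    n_perm: int
    seed: int | None


def cadm_test(
    matrices: list[DistanceMatrix],
    n_perm: int | str = 1000,
    seed: int | None = None,
    permute_all: bool = True,
) -> CADMResult:
    """CADM global and a posteriori congruence tests.

    ``permute_all=True`` permutes the objects of every matrix independently
    in the global null (set False to hold the first matrix fixed as a
    reference).  ``n_perm="exhaustive"`` enumerates all n! permutations of
    the second matrix (m = 2 only; valid because W is invariant under
    simultaneous relabeling of all matrices).
    """
    if len(matrices) < 2:
        raise ValueError("CADM needs at least 2 matrices")
    check_aligned(*matrices)
    m = len(matrices)
    n = matrices[0].n
    iu = np.triu_indices(n, k=1)

    # ranked square matrices: ranks live on the off-diagonal cells, so object
    # permutation of a matrix is object permutation of its rank matrix
    rank_sq = []
    R = []
    for dm in matrices:
        v = dm.values[iu]
        if np.ptp(v) == 0:
            raise ValueError("constant matrix: ranks undefined")
        rk = rankdata(v)
        sq = np.zeros((n, n))
        sq[iu] = rk
        sq = sq + sq.T
        rank_sq.append(sq)
        R.append(rk)
    R = np.array(R)
    W_obs = kendall_w(R)

    exhaustive = n_perm == "exhaustive"
    if exhaustive and m != 2:
        raise ValueError("exhaustive CADM is supported for m = 2 only")

    rng = np.random.default_rng(seed)
    if exhaustive:
        null_W = []
        for p in itertools.permutations(range(n)):
            p = np.array(p)
            rows = np.array([R[0], rank_sq[1][np.ix_(p, p)][iu]])
            null_W.append(kendall_w(rows))
        null_W = np.array(null_W)
        p_global = float(np.sum(null_W >= W_obs) / len(null_W))
        n_used = len(null_W)
    else:
        n_perm = int(n_perm)
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        null_W = np.empty(n_perm)
        for it in range(n_perm):
            rows = np.empty_like(R)
            for k in range(m):
                if k == 0 and not permute_all:
                    rows[k] = R[k]
                else:
                    p = rng.permutation(n)
                    rows[k] = rank_sq[k][np.ix_(p, p)][iu]
            null_W[it] = kendall_w(rows)
        p_global = (1 + int(np.sum(null_W >= W_obs))) / (n_perm + 1)
        n_used = n_perm

    # a posteriori: matrix k's ranks vs mean ranks of the others
    posthoc = []
    for k in range(m):
        others = np.mean([R[j] for j in range(m) if j != k], axis=0)
        r_obs = _pearson(R[k], others)
        if exhaustive:
            null_r = np.array([
                _pearson(rank_sq[k][np.ix_(np.array(p), np.array(p))][iu], others)
                for p in itertools.permutations(range(n))
            ])
            p_k = float(np.sum(null_r >= r_obs) / len(null_r))
        else:
            null_r = np.empty(n_used)
            for it in range(n_used):
                p = rng.permutation(n)
                null_r[it] = _pearson(rank_sq[k][np.ix_(p, p)][iu], others)
            p_k = (1 + int(np.sum(null_r >= r_obs))) / (n_used + 1)
        posthoc.append((r_obs, p_k))
    return CADMResult(W=W_obs, p_global=p_global, posthoc=posthoc, n_perm=n_used, seed=seed)


# ----------------------------------------------------------------------
# Report
# ----------------------------------------------------------------------

def congruence_report(
    morph: DistanceMatrix,
    inputs: dict,
    mode: str = "raw",
    genotype_map: dict[str, list[str]] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One row of Mantel + CADM statistics per genetic input.

    ``inputs`` maps a name to either a ``DistanceMatrix`` or a dendropy
    ``Tree``.  With ``mode="topological"``, trees are converted to
    unit-branch-length cophenetic (edge-count) distances — collapsed to
    sample level via ``genotype_map`` when given — and the morphological
    matrix is replaced by the topological distances of its own UPGMA
    dendrogram.  Errors in one comparison are reported in that row's
    ``error`` column; remaining rows are still computed.
    """
    from .treespace import average_linkage_tree, topological_distances, collapse_allele_distances

    if mode not in ("raw", "topological"):
        raise ValueError(f"unknown mode {mode!r}")
    morph_used = morph
    if mode == "topological":
        morph_used = topological_distances(average_linkage_tree(morph))

    rows = []
    for name, obj in inputs.items():
        row = {"comparison": name, "mode": mode, "n_perm": n_perm, "seed": seed, "error": ""}
        try:
            if isinstance(obj, DistanceMatrix):
                dm = obj
                if mode == "topological":
                    dm = topological_distances(average_linkage_tree(obj))
            else:  # a tree
                dm = topological_distances(obj)
                if genotype_map is not None:
                    dm = collapse_allele_distances(dm, genotype_map)
            dm = dm.reorder(morph_used.labels)
            mres = mantel_test(morph_used, dm, n_perm=n_perm, seed=seed)
            cres = cadm_test([morph_used, dm], n_perm=n_perm, seed=seed)
            row.update(
                mantel_Z=mres.Z, mantel_r=mres.r, mantel_t=mres.t, mantel_p=mres.p,
                kendall_W=cres.W, cadm_p=cres.p_global,
                cadm_correlation=cres.posthoc[1][0], cadm_posthoc_p=cres.posthoc[1][1],
            )
        except (ValueError, KeyError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    cols = ["comparison", "mode", "mantel_Z", "mantel_r", "mantel_t", "mantel_p",
            "kendall_W", "cadm_p", "cadm_correlation", "cadm_posthoc_p",
            "n_perm", "seed", "error"]
    df = pd.DataFrame(rows)
    return df.reindex(columns=[c for c in cols if c in df.columns])
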
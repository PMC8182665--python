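"""Herd clustering on a precomputed dissimilarity matrix.

Three of the four competing strategies live here: Ward agglomerative
hierarchical clustering (the ward.D2 convention, i.e. the Lance-Williams
update applied to squared dissimilarities), partitioning around medoids
(BUILD + SWAP to a local optimum) and fuzzy clustering of a dissimilarity
matrix with membership exponent r.  The fourth strategy - clustering of
variables followed by AHC on synthetic variables - is in
:mod:`herdclust.varclust`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .survey import DissimilarityMatrix

__all__ = [
    "MergeTree",
    "Partition",
    "MembershipMatrix",
    "ahc_ward",
    "cut_tree",
    "pam",
    "fuzzy_cluster",
]


@dataclass
class MergeTree:
    """Agglomerative merge sequence in scipy linkage form.

    ``linkage`` is the (n-1) x 4 scipy matrix: leaves are numbered
    0..n-1, the cluster created at step s gets id n+s, and column 2 holds the
    merge height.
    """

    leaf_ids: list
    linkage: np.ndarray

    def __post_init__(self):
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 rows")

    @property
    def n(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage[:, :3], columns=["left", "right", "height"]
        ).astype({"left": int, "right": int})


@dataclass
class Partition:
    """Hard assignment of herds to k nonempty clusters (labels 0..k-1)."""

    herd_ids: list
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.herd_ids):
            raise ValueError("one label per herd required")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            # normalize arbitrary label values to 0..k-1 preserving order of
            # first appearance
            _, self.labels = np.unique(self.labels, return_inverse=True)

    @property
    def k(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def n(self) -> int:
        return len(self.herd_ids)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.herd_ids, name="cluster")

    def cluster_members(self, c: int) -> list:
        return [h for h, l in zip(self.herd_ids, self.labels) if l == c]

    def relabel_by_size(self) -> "Partition":
        """Return an equivalent partition with clusters ordered by size."""
        sizes = np.bincount(self.labels)
        order = np.argsort(-sizes, kind="stable")
        remap = np.empty_like(order)
        remap[order] = np.arange(len(order))
        return Partition(self.herd_ids, remap[self.labels])

    def to_csv(self, path) -> None:
        self.as_series().rename_axis("herd_id").to_csv(path)


@dataclass
class MembershipMatrix:
    """Fuzzy herd x cluster membership; each row is a probability vector."""

    herd_ids: list
    U: np.ndarray
    r: float
    converged: bool = True
    objective: float = np.nan
    history: list = field(default_factory=list)

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        if self.r <= 1:
            raise ValueError("fuzziness exponent r must exceed 1")
        if np.any(self.U < -1e-12):
            raise ValueError("memberships must be nonnegative")
        if not np.allclose(self.U.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")

    @property
    def k(self) -> int:
        return self.U.shape[1]

    def crisp(self) -> Partition:
        """Hard partition by row-wise argmax (ties to the lowest cluster)."""
        return Partition(self.herd_ids, np.argmax(self.U, axis=1))


def ahc_ward(D: DissimilarityMatrix) -> MergeTree:
    """Ward agglomerative clustering of a dissimilarity matrix (ward.D2)."""
    if D.n < 2:
        raise ValueError("need at least 2 herds to cluster")
    Z = sch.linkage(squareform(D.D, checks=False), method="ward")
    return MergeTree(D.herd_ids, Z)


def cut_tree(tree: MergeTree, k: int) -> Partition:
    """Partition obtained by undoing the last k-1 merges of the tree."""
    if not 1 <= k <= tree.n:
        raise ValueError(f"k={k} out of range 1..{tree.n}")
    labels = sch.cut_tree(tree.linkage, n_clusters=k).ravel()
    return Partition(tree.leaf_ids, labels)


def _pam_objective(D: np.ndarray, medoids: np.ndarray) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def pam(
    D: DissimilarityMatrix, k: int, exact_limit: int = 20_000
) -> tuple[Partition, list, float]:
    """Partitioning around medoids: BUILD, first-improvement SWAP, and an
    exhaustive refinement at desk scale.

    Returns the partition, the medoid herd ids and the final objective
    (total dissimilarity of every herd to its nearest medoid).  SWAP stops
    at a local optimum, which for rare instances is not the global one; when
    the medoid-set space is enumerable (C(n, k) <= ``exact_limit``) the
    result is therefore refined by full enumeration, making it provably
    optimal.  Fully deterministic: candidate scans run in index order and
    ties keep the earliest candidate.
    """
    import itertools
    from math import comb

    n = D.n
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n={n}")
    M = D.D
    # BUILD: first medoid minimizes total distance, then greedily add the
    # candidate with the largest reduction of the objective.
    medoids = [int(np.argmin(M.sum(axis=1)))]
    while len(medoids) < k:
        nearest = M[:, medoids].min(axis=1)
        best_gain, best_c = -np.inf, None
        for c in range(n):
            if c in medoids:
                continue
            gain = np.maximum(nearest - M[:, c], 0.0).sum()
            if gain > best_gain:
                best_gain, best_c = gain, c
        medoids.append(best_c)
    medoids = np.array(sorted(medoids))
    obj = _pam_objective(M, medoids)
    # SWAP to a local optimum, first improvement in index order
    improved = True
    while improved:
        improved = False
        for mi in range(k):
            for c in range(n):
                if c in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = c
                cand_obj = _pam_objective(M, cand)
                if cand_obj < obj - 1e-12:
                    medoids, obj = np.sort(cand), cand_obj
                    improved = True
                    break
            if improved:
                break
    if comb(n, k) <= exact_limit:
        for cand in itertools.combinations(range(n), k):
            cand = np.array(cand)
            cand_obj = _pam_objective(M, cand)
            if cand_obj < obj - 1e-12:
                medoids, obj = cand, cand_obj
    labels = np.argmin(M[:, medoids], axis=1)
    labels[medoids] = np.arange(k)  # medoids belong to their own cluster
    return (
        Partition(D.herd_ids, labels),
        [D.herd_ids[m] for m in medoids],
        obj,
    )


def _fanny_objective(M: np.ndarray, U: np.ndarray, r: float) -> float:
    ur = U**r
    denom = ur.sum(axis=0)
    num = np.einsum("iv,ij,jv->v", ur, M, ur)
    return float((num / (2.0 * denom)).sum())


def fuzzy_cluster(
    D: DissimilarityMatrix,
    k: int,
    r: float = 1.1,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[MembershipMatrix, Partition]:
    """Fuzzy clustering of a dissimilarity matrix (FANNY-type objective).

    Minimizes sum_v [sum_ij u_iv^r u_jv^r d(i,j)] / [2 sum_j u_jv^r] by
    iterative membership updates.  The exponent ``r`` > 1 controls the
    degree of fuzziness (r -> 1 approaches a crisp partition).  Updates that
    would increase the objective are damped toward the previous memberships,
    so the recorded objective history is nonincreasing; if no damped step
    improves, iteration stops at the current (locally optimal) memberships.
    """
    n = D.n
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n={n}")
    if r <= 1:
        raise ValueError("r must exceed 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    M = D.D
    U = np.full((n, k), 1.0 / k) + 0.1 / k * rng.random((n, k))
    U /= U.sum(axis=1, keepdims=True)
    obj = _fanny_objective(M, U, r)
    history = [obj]
    converged = False
    expo = 1.0 / (r - 1.0)
    for _ in range(max_iter):
        ur = U**r
        denom = ur.sum(axis=0)  # (k,)
        P = (M @ ur) / denom  # mean weighted distance of i to cluster v
        q = np.einsum("iv,ij,jv->v", ur, M, ur) / (2.0 * denom**2)
        A = P - q[None, :]
        # closed-form stationary update; nonpositive A => crisp assignment
        Unew = np.zeros_like(U)
        bad = A <= 1e-300
        any_bad = bad.any(axis=1)
        with np.errstate(over="ignore"):
            W = np.where(A > 1e-300, A, 1.0) ** (-expo)
        Unew[~any_bad] = W[~any_bad] / W[~any_bad].sum(axis=1, keepdims=True)
        for i in np.where(any_bad)[0]:
            Unew[i, int(np.argmin(A[i]))] = 1.0
        # guard monotonicity by damping toward the previous iterate
        step_obj = _fanny_objective(M, Unew, r)
        trials = 0
        while step_obj > obj and trials < 30:
            Unew = 0.5 * (Unew + U)
            step_obj = _fanny_objective(M, Unew, r)
            trials += 1
        if step_obj > obj:
            converged = True
            break
        rel_change = (obj - step_obj) / max(abs(obj), 1.0)
        U, obj = Unew, step_obj
        history.append(obj)
        if rel_change < tol:
            converged = True
            break
    else:
        import warnings

        warnings.warn("fuzzy clustering hit max_iter without converging", stacklevel=2)
    mem = MembershipMatrix(
        D.herd_ids, U, r, converged=converged, objective=obj, history=history
    )
    return mem, mem.crisp()
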
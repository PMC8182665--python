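"""Clustering of variables with synthetic variables (CoVAHC).

Variables are grouped agglomeratively so that each group stays as
*homogeneous* as possible.  The homogeneity of a group is the sum of squared
Pearson correlations (quantitative members) and correlation ratios
(qualitative members) with the group's *synthetic variable* - the first
principal component of a mixed-data PCA built from standardized quantitative
columns and centered level indicators scaled by the inverse square root of
the level frequency.  With that scaling the homogeneity equals the leading
eigenvalue of the group's mixed-data matrix, which is what the merge search
exploits.  Herds are then clustered by Ward AHC on the Euclidean geometry of
the synthetic-variable scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import MergeTree, Partition, ahc_ward, cut_tree
from .survey import DissimilarityMatrix, TypedSurvey

__all__ = [
    "VariableCluster",
    "VariableClusterTree",
    "homogeneity",
    "synthetic_variable",
    "cluster_of_variables",
    "covahc",
    "score_dissimilarity",
]


@dataclass
class VariableCluster:
    """A group of variables, its homogeneity and its synthetic scores."""

    members: list[str]
    homogeneity: float
    synthetic_scores: pd.Series

    def __post_init__(self):
        if self.homogeneity > len(self.members) + 1e-8:
            raise ValueError("homogeneity cannot exceed the number of member variables")


def _mixed_columns(survey: TypedSurvey, names) -> np.ndarray:
    """Mixed-data PCA matrix for the given variables (n_herds x n_columns).

    Quantitative and ordinal variables give one population-standardized
    column (ordinal levels are replaced by their ranks); every level of a
    qualitative variable gives a centered indicator column divided by the
    square root of the level's relative frequency.  Missing entries are
    mean/mode imputed with a warning: the merge search needs a complete
    matrix.
    """
    cols = []
    n = survey.n_herds
    for name in names:
        s = survey.spec(name)
        col = survey.values[name]
        if s.is_quantitative or s.vtype == "ordinal":
            if s.vtype == "ordinal":
                x = col.map({lev: i for i, lev in enumerate(s.levels)}).to_numpy(dtype=float)
            else:
                x = col.to_numpy(dtype=float)
            if np.isnan(x).any():
                warnings.warn(f"mean-imputing missing values of {name!r}", stacklevel=3)
                x = np.where(np.isnan(x), np.nanmean(x), x)
            sd = x.std()
            if sd == 0:
                raise ValueError(f"variable {name!r} is constant")
            cols.append((x - x.mean()) / sd)
        else:
            if col.isna().any():
                warnings.warn(f"mode-imputing missing values of {name!r}", stacklevel=3)
                col = col.fillna(col.mode().iloc[0])
            codes, levels = pd.factorize(col, sort=True)
            if len(levels) < 2:
                raise ValueError(f"variable {name!r} is constant")
            G = np.eye(len(levels))[codes]
            p = G.mean(axis=0)
            cols.append(((G - p) / np.sqrt(p)).T)
    return np.column_stack([c.T if c.ndim > 1 else c for c in cols]).reshape(n, -1)


def _lambda1(M: np.ndarray) -> float:
    """Leading eigenvalue of M'M / n (= homogeneity of the variable group)."""
    n, m = M.shape
    if m <= n:
        w = np.linalg.eigvalsh(M.T @ M)
    else:
        w = np.linalg.eigvalsh(M @ M.T)
    return float(w[-1]) / n


def synthetic_variable(survey: TypedSurvey, names) -> pd.Series:
    """First mixed-data principal component of a group of variables.

    Scores are centered and scaled so their population variance equals the
    leading eigenvalue; the sign is fixed so that the loading on the first
    column of the mixed-data matrix is nonnegative (ties fall through to the
    next column).
    """
    names = list(names)
    if len(names) < 1:
        raise ValueError("need at least one variable")
    if survey.n_herds < 3:
        raise ValueError("need at least 3 herds")
    M = _mixed_columns(survey, names)
    _, _, Vt = np.linalg.svd(M, full_matrices=False)
    v1 = Vt[0]
    nz = np.flatnonzero(np.abs(v1) > 1e-12)
    if nz.size and v1[nz[0]] < 0:
        v1 = -v1
    # population variance of the scores equals the leading eigenvalue
    return pd.Series(M @ v1, index=survey.values.index, name="+".join(names))


def homogeneity(survey: TypedSurvey, names, synthetic: pd.Series | np.ndarray) -> float:
    """Sum of squared correlations / correlation ratios with the synthetic scores.

    H = sum_quant r^2(x, f) + sum_qual eta^2(f | x), where eta^2 is the
    between-level share of the variance of the scores f.  Computed directly
    from the data, independently of any eigen decomposition.
    """
    f = np.asarray(synthetic, dtype=float)
    if f.std() == 0:
        raise ValueError("synthetic scores are constant")
    H = 0.0
    for name in names:
        s = survey.spec(name)
        col = survey.values[name]
        if s.is_quantitative or s.vtype == "ordinal":
            if s.vtype == "ordinal":
                x = col.map({lev: i for i, lev in enumerate(s.levels)}).to_numpy(dtype=float)
            else:
                x = col.to_numpy(dtype=float)
            obs = ~np.isnan(x)
            H += float(np.corrcoef(x[obs], f[obs])[0, 1] ** 2)
        else:
            col = col.fillna(col.mode().iloc[0]) if col.isna().any() else col
            total = ((f - f.mean()) ** 2).sum()
            between = 0.0
            for _, idx in col.groupby(col, observed=True).groups.items():
                sub = f[col.index.get_indexer(idx)]
                between += len(sub) * (sub.mean() - f.mean()) ** 2
            H += float(between / total)
    return H


@dataclass
class VariableClusterTree:
    """Full variable-merge sequence with synthetic scores on demand."""

    survey: TypedSurvey
    merges: list[tuple[frozenset, frozenset, float]]  # (A, B, loss of homogeneity)

    @property
    def variable_names(self) -> list[str]:
        return [s.name for s in self.survey.specs]

    @property
    def losses(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def aggregated_homogeneity(self) -> np.ndarray:
        """Total homogeneity after 0, 1, ..., p-1 merges (starts at p)."""
        p = len(self.variable_names)
        return p - np.concatenate([[0.0], np.cumsum(self.losses)])

    def default_n_clusters(self) -> int:
        """Default number of variable clusters to retain.

        Kaiser-Guttman rule on the full mixed-data PCA: the number of
        eigenvalues above the average eigenvalue, i.e. the number of
        dimensions that carry more information than an average one.  (The
        raw homogeneity losses cannot decide this: along any nested merge
        sequence the largest loss sits at the very last merges.)
        """
        p = len(self.variable_names)
        if p == 1:
            return 1
        M = _mixed_columns(self.survey, self.variable_names)
        n = M.shape[0]
        lam = np.linalg.eigvalsh(M @ M.T / n)[::-1]
        lam = lam[lam > 1e-10]
        return int(np.clip((lam > lam.mean()).sum(), 1, p))

    def partition(self, n_clusters: int) -> list[frozenset]:
        p = len(self.variable_names)
        if not 1 <= n_clusters <= p:
            raise ValueError("n_clusters out of range")
        clusters = {frozenset([v]) for v in self.variable_names}
        for A, B, _ in self.merges[: p - n_clusters]:
            clusters.discard(A)
            clusters.discard(B)
            clusters.add(A | B)
        return sorted(clusters, key=lambda c: min(self.variable_names.index(v) for v in c))

    def clusters(self, n_clusters: int) -> list[VariableCluster]:
        out = []
        for group in self.partition(n_clusters):
            names = sorted(group, key=self.variable_names.index)
            scores = synthetic_variable(self.survey, names)
            out.append(VariableCluster(names, homogeneity(self.survey, names, scores), scores))
        return out

    def score_matrix(self, n_clusters: int) -> pd.DataFrame:
        """Herds x variable-clusters synthetic-score matrix."""
        cl = self.clusters(n_clusters)
        return pd.DataFrame(
            {f"sv{j + 1}": c.synthetic_scores for j, c in enumerate(cl)}
        )


def cluster_of_variables(survey: TypedSurvey) -> VariableClusterTree:
    """Agglomerative clustering of variables by minimal loss of homogeneity.

    Starts from singleton variable clusters (each with H = 1) and at every
    step merges the pair (A, B) minimizing H(A) + H(B) - H(A u B); ties go
    to the lexicographically earliest pair in survey column order.
    """
    names = [s.name for s in survey.specs]
    if len(names) < 2:
        raise ValueError("need at least 2 variables")
    mats = {frozenset([v]): _mixed_columns(survey, [v]) for v in names}
    H = {c: _lambda1(M) for c, M in mats.items()}
    order = {v: i for i, v in enumerate(names)}

    def key(c: frozenset) -> int:
        return min(order[v] for v in c)

    clusters = sorted(mats, key=key)
    pair_cost: dict[frozenset, tuple[float, float, np.ndarray]] = {}

    def eval_pair(A: frozenset, B: frozenset):
        M = np.hstack([mats[A], mats[B]])
        h = _lambda1(M)
        return H[A] + H[B] - h, h, M

    for i, A in enumerate(clusters):
        for B in clusters[i + 1 :]:
            pair_cost[A | B] = eval_pair(A, B)

    merges = []
    while len(clusters) > 1:
        best = None
        for i, A in enumerate(clusters):
            for B in clusters[i + 1 :]:
                cost = pair_cost[A | B][0]
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, A, B)
        cost, A, B = best
        _, hAB, MAB = pair_cost[A | B]
        merges.append((A, B, cost))
        for C in clusters:
            if C is not A and C is not B:
                pair_cost.pop(C | A, None)
                pair_cost.pop(C | B, None)
        pair_cost.pop(A | B, None)
        clusters = [c for c in clusters if c not in (A, B)]
        new = A | B
        mats[new], H[new] = MAB, hAB
        del mats[A], mats[B], H[A], H[B]
        for C in clusters:
            pair_cost[C | new] = eval_pair(C, new)
        clusters.append(new)
        clusters.sort(key=key)
    return VariableClusterTree(survey, merges)


def score_dissimilarity(scores: pd.DataFrame) -> DissimilarityMatrix:
    """Euclidean distances between herds in synthetic-variable space,
    rescaled to [0, 1] by the maximum pairwise distance."""
    X = scores.to_numpy(dtype=float)
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    mx = D.max()
    if mx > 0:
        D = D / mx
    return DissimilarityMatrix(list(scores.index), D)


def covahc(
    survey: TypedSurvey,
    k: int,
    n_var_clusters: int | None = None,
    tree: VariableClusterTree | None = None,
) -> tuple[Partition, pd.DataFrame, MergeTree]:
    """Clustering of variables followed by Ward AHC of the herds.

    Builds the variable-cluster tree (unless one is passed in), extracts the
    synthetic-score matrix at ``n_var_clusters`` (default: the level just
    before the largest homogeneity drop), then applies Ward AHC to the
    Euclidean distances of the scores and cuts at ``k`` herd clusters.
    Returns (partition, score matrix, herd merge tree).
    """
    if tree is None:
        tree = cluster_of_variables(survey)
    if n_var_clusters is None:
        n_var_clusters = tree.default_n_clusters()
    scores = tree.score_matrix(n_var_clusters)
    D = score_dissimilarity(scores)
    herd_tree = ahc_ward(D)
    return cut_tree(herd_tree, k), scores, herd_tree
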
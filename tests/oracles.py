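"""Independent brute-force reference implementations used only by tests.

Each oracle is written directly from the defining formula, with plain
loops, and shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def naive_gower(values: pd.DataFrame, specs) -> np.ndarray:
    """Pairwise modified Gower dissimilarity by explicit double loop."""
    n = len(values)
    ranges = {}
    numeric = {}
    for s in specs:
        if s.vtype in ("quantitative", "ordinal"):
            if s.vtype == "ordinal":
                rank = {lev: i for i, lev in enumerate(s.levels)}
                x = np.array(
                    [np.nan if pd.isna(v) else rank[v] / (len(s.levels) - 1)
                     for v in values[s.name]], dtype=float)
            else:
                x = values[s.name].to_numpy(dtype=float)
            numeric[s.name] = x
            obs = x[~np.isnan(x)]
            ranges[s.name] = obs.max() - obs.min() if obs.size else 0.0
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for s in specs:
                a, b = values.iloc[i][s.name], values.iloc[j][s.name]
                if pd.isna(a) or pd.isna(b):
                    continue
                w = s.weight
                if s.vtype in ("quantitative", "ordinal"):
                    xa, xb = numeric[s.name][i], numeric[s.name][j]
                    r = ranges[s.name]
                    d = abs(xa - xb) / r if r > 0 else 0.0
                elif s.vtype == "binary_asymmetric":
                    absent = s.levels[0] if s.levels else 0
                    if a == absent and b == absent:
                        continue
                    d = 0.0 if a == b else 1.0
                else:
                    d = 0.0 if a == b else 1.0
                num += w * d
                den += w
            D[i, j] = num / den if den > 0 else np.nan
    return D


def naive_silhouette(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Rousseeuw silhouette widths by explicit loops."""
    n = len(labels)
    ks = np.unique(labels)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == c])
            for c in ks if c != labels[i]
        )
        m = max(a, b)
        s[i] = 0.0 if m == 0 else (b - a) / m
    return s


def naive_ward_d2(D: np.ndarray):
    """Ward agglomeration on squared dissimilarities (Lance-Williams).

    Returns the sorted merge heights (ward.D2 convention: heights are the
    square roots of the updated squared distances).
    """
    n = D.shape[0]
    d2 = D.astype(float) ** 2
    active = {i: [i] for i in range(n)}
    d2 = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    while len(active) > 1:
        (i, j), val = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(np.sqrt(val))
        ni, nj = len(active[i]), len(active[j])
        merged = active[i] + active[j]
        for k in list(active):
            if k in (i, j):
                continue
            nk = len(active[k])
            dki = d2[tuple(sorted((k, i)))]
            dkj = d2[tuple(sorted((k, j)))]
            new = ((ni + nk) * dki + (nj + nk) * dkj - nk * val) / (ni + nj + nk)
            d2[tuple(sorted((k, i)))] = new
        del active[j]
        active[i] = merged
        d2 = {key: v for key, v in d2.items() if j not in key}
    return np.sort(np.array(heights))


def pam_bruteforce(D: np.ndarray, k: int) -> float:
    """Optimal PAM objective by exhaustive search over all medoid sets."""
    n = D.shape[0]
    best = np.inf
    for medoids in itertools.combinations(range(n), k):
        obj = D[:, list(medoids)].min(axis=1).sum()
        best = min(best, obj)
    return float(best)


def tabular_A(table: pd.DataFrame) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    ``table`` must be topologically sorted (parents before offspring) with
    columns animal/sire/dam; unknown parents are NaN.
    """
    animals = list(table["animal"])
    pos = {a: i for i, a in enumerate(animals)}
    n = len(animals)
    A = np.zeros((n, n))
    for i, (_, row) in enumerate(table.iterrows()):
        s = pos.get(row["sire"]) if pd.notna(row["sire"]) else None
        d = pos.get(row["dam"]) if pd.notna(row["dam"]) else None
        A[i, i] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
        for j in range(i):
            val = 0.0
            if s is not None:
                val += 0.5 * A[j, s]
            if d is not None:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return A


def random_dissimilarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix with zero diagonal and entries in (0, 1)."""
    M = rng.random((n, n))
    D = (M + M.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D
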
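"""Silhouette widths, the ASW model-selection sweep and misclassification.

The average silhouette width (ASW) is the single evaluation criterion used
to compare the four clustering strategies and to pick the number of herd
clusters: for every herd i, a(i) is the mean dissimilarity to its own
cluster (excluding itself), b(i) the smallest mean dissimilarity to any
other cluster, and s(i) = (b(i) - a(i)) / max(a(i), b(i)).  Herds alone in
their cluster get s(i) = 0 by convention.  Herds with negative s(i) sit
closer to another cluster than to their own and are flagged as
misclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import Partition, ahc_ward, cut_tree, fuzzy_cluster, pam
from .survey import DissimilarityMatrix, TypedSurvey, gower_matrix
from .varclust import cluster_of_variables, covahc, score_dissimilarity

__all__ = [
    "SilhouetteReport",
    "SweepResult",
    "silhouette",
    "asw_sweep",
    "misclassification_report",
    "DEFAULT_METHODS",
]

DEFAULT_METHODS = ("ahc", "pam", "fzc", "covahc")


@dataclass
class SilhouetteReport:
    """Per-herd silhouette widths s(i), per-cluster means and the ASW."""

    herd_ids: list
    labels: np.ndarray
    s: np.ndarray
    trivial: bool = False  # k == 1 or k == n: all-zero report

    @property
    def asw(self) -> float:
        return float(np.mean(self.s))

    def per_cluster(self) -> pd.Series:
        return pd.Series(self.s).groupby(self.labels).mean().rename("mean_s")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"herd_id": self.herd_ids, "cluster": self.labels, "s": self.s}
        ).set_index("herd_id")


def silhouette(D: DissimilarityMatrix, p: Partition) -> SilhouetteReport:
    """Silhouette widths of a partition on a dissimilarity matrix.

    k = 1 or k = n yield an all-zero report with a warning (there is no
    between- or within-cluster contrast to measure).
    """
    if list(p.herd_ids) != list(D.herd_ids):
        raise ValueError("partition and dissimilarity matrix cover different herds")
    n, k = D.n, p.k
    labels = p.labels
    if k == 1 or k == n:
        warnings.warn(f"silhouette undefined for k={k} with n={n}; returning zeros",
                      stacklevel=2)
        return SilhouetteReport(D.herd_ids, labels, np.zeros(n), trivial=True)
    sizes = np.bincount(labels, minlength=k)
    # mean distance of every herd to every cluster
    sums = np.zeros((n, k))
    for c in range(k):
        sums[:, c] = D.D[:, labels == c].sum(axis=1)
    s = np.zeros(n)
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue  # singleton convention: s = 0
        a = sums[i, c] / (sizes[c] - 1)
        other = [sums[i, d] / sizes[d] for d in range(k) if d != c]
        b = min(other)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return SilhouetteReport(D.herd_ids, labels, s)


def misclassification_report(report: SilhouetteReport) -> pd.DataFrame:
    """Herds with strictly negative silhouette, sorted worst first."""
    frame = report.to_frame()
    bad = frame[frame["s"] < 0].sort_values("s")
    return bad


@dataclass
class SweepResult:
    """ASW per (method, k), the selected configuration and all partitions."""

    table: pd.DataFrame  # rows = method, columns = k
    selected: tuple[str, int]
    partitions: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def selected_partition(self) -> Partition:
        return self.partitions[self.selected]

    def to_long(self) -> pd.DataFrame:
        long = self.table.reset_index().melt(
            id_vars="method", var_name="k", value_name="asw"
        )
        long["k"] = long["k"].astype(int)
        return long.dropna(subset=["asw"]).reset_index(drop=True)


def asw_sweep(
    survey: TypedSurvey,
    methods=DEFAULT_METHODS,
    k_range=range(2, 11),
    seed: int = 0,
    fzc_r: float = 1.1,
    n_var_clusters: int | None = None,
    report_covahc_scores: bool = True,
) -> SweepResult:
    """ASW of every clustering method at every k, plus the winning cell.

    Every method - including CoVAHC - is scored on the Gower matrix of the
    survey, so all ASW values share one geometry and the argmax across
    methods is meaningful (the four methods are compared on a single ASW
    axis).  A ``covahc_scores`` row additionally reports CoVAHC silhouettes
    in the synthetic-variable geometry its own AHC step uses (reported,
    never used for selection: principal-component scores systematically
    understate the isolation of very small clusters, and the score-space
    values are not on the Gower scale).  Selection is the argmax ASW cell,
    ties resolved toward the smaller k and then by method order.  A method
    failing at some k leaves the cell missing instead of aborting the sweep.
    """
    k_range = [int(k) for k in k_range]
    if any(k < 2 or k >= survey.n_herds for k in k_range):
        raise ValueError("k_range must lie within 2..n_herds-1")
    D = gower_matrix(survey.standardized())
    rows = {m: {} for m in methods}
    if report_covahc_scores and "covahc" in methods:
        rows["covahc_scores"] = {}
    partitions: dict = {}
    errors: dict = {}

    gower_tree = covahc_tree = var_tree = scores_D = None
    for method in methods:
        for k in k_range:
            try:
                if method == "ahc":
                    if gower_tree is None:
                        gower_tree = ahc_ward(D)
                    part = cut_tree(gower_tree, k)
                    rep = silhouette(D, part)
                elif method == "pam":
                    part, _, _ = pam(D, k)
                    rep = silhouette(D, part)
                elif method == "fzc":
                    _, part = fuzzy_cluster(D, k, r=fzc_r, seed=seed + 7 * k)
                    rep = silhouette(D, part)
                elif method == "covahc":
                    if var_tree is None:
                        var_tree = cluster_of_variables(survey)
                    part, scores, covahc_tree = covahc(
                        survey, k, n_var_clusters=n_var_clusters, tree=var_tree
                    )
                    rep = silhouette(D, part)
                    if report_covahc_scores:
                        if scores_D is None:
                            scores_D = score_dissimilarity(scores)
                        rows["covahc_scores"][k] = silhouette(scores_D, part).asw
                else:
                    raise ValueError(f"unknown clustering method {method!r}")
                rows[method][k] = rep.asw
                partitions[(method, k)] = part
            except Exception as exc:  # noqa: BLE001 - sweep must not crash
                errors[(method, k)] = str(exc)
                rows[method][k] = np.nan
    table = pd.DataFrame(rows).T.reindex(columns=k_range)
    table.index.name = "method"
    # argmax over the competing methods, ties to smaller k then method order
    best, best_val = None, -np.inf
    for k in k_range:
        for method in methods:
            val = table.loc[method, k]
            if np.isfinite(val) and val > best_val + 1e-12:
                best, best_val = (method, k), val
    if best is None:
        raise RuntimeError("every sweep cell failed: " + repr(errors))
    return SweepResult(table, best, partitions, errors)
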
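"""Pedigree BLUP test-day animal model with herd-cluster contemporary groups.

A repeatability animal model for test-day milk yield,

    y = mu + breed + year-season + lactation + CG + f(DIM) + b*CA + a + pe + e,

where the contemporary group (CG) is one of four schemes - herd-test-day
(HTD), herd-cluster-test-day (HCTD), herd-test-month (HTM) or
herd-cluster-test-month (HCTM) - f(DIM) is a fixed third-order Legendre
regression on days in milk, ``a`` is the additive genetic effect with
pedigree covariance sigma_a^2 A and ``pe`` the cow permanent environment.
Variance components come from EM-REML, breeding values from the mixed-model
equations, and reliabilities from prediction error variances
(r^2 = 1 - PEV / sigma_a^2).  Replacing single herds by herd clusters
coarsens the CG definition, raising the number of records per group, which
is the mechanism studied by :func:`compare_cg_models`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .clustering import Partition
from .mixedmodel import (
    LinearMixedModel,
    MMEFit,
    RandomTerm,
    build_fixed_design,
    indicator_matrix,
)

__all__ = [
    "PedigreeTable",
    "ContemporaryGroupAssignment",
    "VarianceComponents",
    "MMESolution",
    "CG_SCHEMES",
    "build_cg",
    "legendre_dim",
    "a_inverse",
    "solve_mme",
    "em_reml",
    "compare_cg_models",
]

CG_SCHEMES = ("HTD", "HCTD", "HTM", "HCTM")


# ---------------------------------------------------------------------------
# pedigree


@dataclass
class PedigreeTable:
    """Animal/sire/dam pedigree; unknown parents are missing (NaN/0/'')."""

    table: pd.DataFrame  # columns animal, sire, dam

    def __post_init__(self):
        t = self.table.copy()
        for col in ("animal", "sire", "dam"):
            if col not in t.columns:
                raise ValueError(f"pedigree needs column {col!r}")
            t[col] = t[col].replace({0: np.nan, "0": np.nan, "": np.nan})
        if t["animal"].duplicated().any():
            raise ValueError("duplicate animals in pedigree")
        self.table = self._topo_sort(t).reset_index(drop=True)

    @staticmethod
    def _topo_sort(t: pd.DataFrame) -> pd.DataFrame:
        order: dict = {}
        parents = t.set_index("animal")[["sire", "dam"]]

        def visit(a, stack):
            if a in order:
                return order[a]
            if a in stack:
                raise ValueError(f"pedigree cycle involving {a!r}")
            if a not in parents.index:
                order[a] = 0
                return 0
            stack.add(a)
            depth = 0
            for p in parents.loc[a]:
                if pd.notna(p):
                    depth = max(depth, visit(p, stack) + 1)
            stack.discard(a)
            order[a] = depth
            return depth

        for a in t["animal"]:
            visit(a, set())
        # parents appearing only as parents become founders
        extra = sorted(
            {p for p in pd.concat([t["sire"], t["dam"]]).dropna()} - set(t["animal"]),
            key=str,
        )
        if extra:
            t = pd.concat(
                [pd.DataFrame({"animal": extra, "sire": np.nan, "dam": np.nan}), t],
                ignore_index=True,
            )
        key = t["animal"].map(order).fillna(0)
        return t.iloc[np.argsort(key, kind="stable")]

    @property
    def animals(self) -> list:
        return list(self.table["animal"])

    @property
    def n(self) -> int:
        return len(self.table)

    def parent_indices(self) -> np.ndarray:
        """(n x 2) integer positions of sire/dam, -1 for unknown."""
        pos = {a: i for i, a in enumerate(self.table["animal"])}
        out = np.full((self.n, 2), -1, dtype=int)
        for i, (s, d) in enumerate(zip(self.table["sire"], self.table["dam"])):
            if pd.notna(s):
                out[i, 0] = pos[s]
            if pd.notna(d):
                out[i, 1] = pos[d]
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PedigreeTable":
        return cls(pd.read_csv(path))


def inbreeding(pedigree: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo recursion."""
    par = pedigree.parent_indices()
    n = pedigree.n
    F = np.zeros(n)
    # L[i] holds the nonzero row of the Cholesky factor of A for animal i,
    # built by tracing ancestors; F_i = sum L_ij^2 * d_j - 1
    d = np.zeros(n)
    for i in range(n):
        s, dd = par[i]
        Fs = F[s] if s >= 0 else -1.0
        Fd = F[dd] if dd >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (Fs + Fd)
        # accumulate A_ii by expanding L-coefficients toward the ancestors
        Aii = 0.0
        todo = {i: 1.0}
        for j in range(i, -1, -1):
            if j not in todo:
                continue
            lj = todo.pop(j)
            Aii += lj * lj * d[j]
            sj, dj = par[j]
            if sj >= 0:
                todo[sj] = todo.get(sj, 0.0) + 0.5 * lj
            if dj >= 0:
                todo[dj] = todo.get(dj, 0.0) + 0.5 * lj
        F[i] = Aii - 1.0
    return F


def a_inverse(pedigree: PedigreeTable) -> sp.csr_matrix:
    """Sparse inverse of the numerator relationship matrix A.

    Henderson's rules with inbreeding from the Meuwissen-Luo recursion.
    Rows/columns follow ``pedigree.animals`` (topologically sorted).
    """
    par = pedigree.parent_indices()
    F = inbreeding(pedigree)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(pedigree.n):
        s, d = par[i]
        Fs = F[s] if s >= 0 else -1.0
        Fd = F[d] if d >= 0 else -1.0
        b = 1.0 / (0.5 - 0.25 * (Fs + Fd))
        add(i, i, b)
        for p in (s, d):
            if p >= 0:
                add(i, p, -b / 2)
                add(p, i, -b / 2)
        for p in (s, d):
            if p >= 0:
                add(p, p, b / 4)
        if s >= 0 and d >= 0:
            add(s, d, b / 4)
            add(d, s, b / 4)
    n = pedigree.n
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------------
# contemporary groups


@dataclass
class ContemporaryGroupAssignment:
    """Record -> CG mapping for one scheme, plus occupancy bookkeeping."""

    scheme: str
    cg: pd.Series  # CG id per retained record (index = record index)
    dropped: pd.Index  # records removed by the under-occupancy policy
    min_size: int
    policy: str
    n_groups_raw: int = 0  # groups the scheme generates before any policy

    @property
    def n_groups(self) -> int:
        return self.cg.nunique()

    def occupancy(self) -> pd.Series:
        return self.cg.value_counts().rename("records")

    def summary(self) -> dict:
        occ = self.occupancy()
        return {
            "scheme": self.scheme,
            "n_cg": int(self.n_groups),
            "n_cg_raw": int(self.n_groups_raw),
            "n_records": int(len(self.cg)),
            "n_dropped": int(len(self.dropped)),
            "min_occupancy": int(occ.min()) if len(occ) else 0,
            "mean_occupancy": float(occ.mean()) if len(occ) else np.nan,
        }


def _cg_keys(records: pd.DataFrame, partition: Partition | None, scheme: str) -> pd.Series:
    scheme = scheme.upper()
    if scheme not in CG_SCHEMES:
        raise ValueError(f"unknown CG scheme {scheme!r}")
    dates = pd.to_datetime(records["test_date"])
    if scheme in ("HTM", "HCTM"):
        time = dates.dt.strftime("%Y-%m")
    else:
        time = dates.dt.strftime("%Y-%m-%d")
    if scheme.startswith("HC"):
        if partition is None:
            raise ValueError(f"scheme {scheme} needs a herd partition")
        cluster_of = dict(zip(partition.herd_ids, partition.labels))
        missing = set(records["herd"]) - set(cluster_of)
        if missing:
            raise ValueError(f"herds without cluster label: {sorted(missing, key=str)}")
        unit = records["herd"].map(cluster_of).map(lambda c: f"hc{c}")
    else:
        unit = records["herd"].astype(str)
    return unit.astype(str) + "|" + time


def build_cg(
    records: pd.DataFrame,
    partition: Partition | None,
    scheme: str,
    min_size: int = 3,
    policy: str = "drop",
) -> ContemporaryGroupAssignment:
    """Assign every test-day record to a contemporary group.

    The CG key is (herd or herd cluster) x (test date or test month)
    depending on ``scheme``.  Groups with fewer than ``min_size`` records
    are handled by ``policy``: ``drop`` removes their records, ``merge``
    pools them with the time-adjacent group of the same herd/cluster unit,
    ``keep`` retains them untouched.
    """
    keys = _cg_keys(records, partition, scheme)
    counts = keys.value_counts()
    n_raw = len(counts)
    small = counts[counts < min_size].index
    dropped = pd.Index([])
    if len(small) and policy == "drop":
        mask = keys.isin(small)
        dropped = records.index[mask]
        keys = keys[~mask]
    elif len(small) and policy == "merge":
        # pool undersized groups forward in time within the same unit
        frame = pd.DataFrame({"key": keys})
        frame[["unit", "time"]] = frame["key"].str.rsplit("|", n=1, expand=True)
        merged = {}
        for unit, sub in frame.groupby("unit"):
            times = sorted(sub["time"].unique())
            sizes = {t: (sub["time"] == t).sum() for t in times}
            current: list[str] = []
            total = 0
            for t in times:
                current.append(t)
                total += sizes[t]
                if total >= min_size:
                    for tt in current:
                        merged[(unit, tt)] = f"{unit}|{current[0]}..{t}" if len(current) > 1 else f"{unit}|{t}"
                    current, total = [], 0
            if current:  # leftover tail joins the previous group
                prev = merged.get((unit, times[-len(current) - 1])) if len(times) > len(current) else None
                label = prev or f"{unit}|{current[0]}..{current[-1]}"
                for tt in current:
                    merged[(unit, tt)] = label
        keys = frame.apply(lambda r: merged[(r["unit"], r["time"])], axis=1)
    elif policy not in ("drop", "merge", "keep"):
        raise ValueError(f"unknown under-occupancy policy {policy!r}")
    return ContemporaryGroupAssignment(
        scheme.upper(), keys, dropped, min_size, policy, n_groups_raw=n_raw
    )


# ---------------------------------------------------------------------------
# Legendre covariates


def legendre_dim(dim, order: int = 3, window: tuple[float, float] = (5.0, 365.0)) -> np.ndarray:
    """Legendre polynomial covariates of days in milk.

    DIM is mapped to t = 2 (dim - min) / (max - min) - 1 on the configured
    lactation window and the first ``order`` + 1 Legendre polynomials
    (1, t, (3t^2-1)/2, (5t^3-3t)/2, ...) are evaluated.  Values outside the
    window are clamped to its edge with a warning.  Returns shape
    (len(dim), order + 1) for array input, (order + 1,) for a scalar.
    """
    scalar = np.isscalar(dim)
    x = np.atleast_1d(np.asarray(dim, dtype=float))
    lo, hi = window
    if np.any((x < lo) | (x > hi)):
        warnings.warn("DIM outside the lactation window clamped to its edge",
                      stacklevel=2)
        x = np.clip(x, lo, hi)
    t = 2.0 * (x - lo) / (hi - lo) - 1.0
    cols = [np.ones_like(t), t]
    for p in range(2, order + 1):
        cols.append(((2 * p - 1) * t * cols[-1] - (p - 1) * cols[-2]) / p)
    out = np.column_stack(cols[: order + 1])
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# variance components and MME solutions


@dataclass
class VarianceComponents:
    """Additive, permanent-environment and residual variances."""

    sigma_a2: float
    sigma_pe2: float
    sigma_e2: float
    se_h2: float | None = None

    def __post_init__(self):
        if min(self.sigma_a2, self.sigma_pe2, self.sigma_e2) < 0:
            raise ValueError("variance components must be nonnegative")

    @property
    def total(self) -> float:
        return self.sigma_a2 + self.sigma_pe2 + self.sigma_e2

    @property
    def h2(self) -> float:
        return self.sigma_a2 / self.total

    @property
    def repeatability(self) -> float:
        return (self.sigma_a2 + self.sigma_pe2) / self.total

    def as_dict(self) -> dict:
        return {
            "animal": self.sigma_a2,
            "pe": self.sigma_pe2,
            "residual": self.sigma_e2,
        }

    @classmethod
    def from_dict(cls, d: dict, se_h2=None) -> "VarianceComponents":
        return cls(d["animal"], d["pe"], d["residual"], se_h2)


@dataclass
class MMESolution:
    """BLUE/BLUP solutions of one genetic-evaluation run."""

    fixed: pd.Series
    ebv: pd.Series  # every pedigree animal
    pe: pd.Series  # animals with records
    pev: pd.Series
    reliability: pd.Series
    vc: VarianceComponents
    fit: MMEFit
    cg: ContemporaryGroupAssignment
    records_used: pd.Index

    def sires_with_daughter_records(self, pedigree: PedigreeTable,
                                    records: pd.DataFrame) -> list:
        """Sires having >=1 daughter with >=1 retained test-day record."""
        recorded = set(records.loc[self.records_used, "animal"])
        t = pedigree.table
        daughters = t[t["animal"].isin(recorded) & t["sire"].notna()]
        return sorted(daughters["sire"].unique(), key=str)


def _genetic_model(
    records: pd.DataFrame,
    cg: ContemporaryGroupAssignment,
    pedigree: PedigreeTable,
    trait: str,
    dim_window: tuple[float, float],
) -> tuple[LinearMixedModel, pd.DataFrame]:
    from .traits import year_season  # shared season definition

    if len(cg.cg) == 0:
        raise ValueError(
            "no records remain after the contemporary-group policy; "
            "lower min_size or choose the merge policy"
        )
    used = records.loc[cg.cg.index].copy()
    used["cg"] = cg.cg
    used["ys"] = pd.to_datetime(used["calving_date"]).map(
        lambda d: year_season(d, with_year=True)
    )
    y = used[trait].to_numpy(dtype=float)
    leg = legendre_dim(used["dim"].to_numpy(dtype=float), order=3, window=dim_window)
    design = build_fixed_design(
        used,
        factors=["breed", "ys", "lactation", "cg"],
        covariates=["calving_age"],
        covariate_columns={"legdim": leg[:, 1:]},  # P0 is the intercept
    )
    animals = pedigree.animals
    apos = {a: i for i, a in enumerate(animals)}
    try:
        acodes = np.array([apos[a] for a in used["animal"]])
    except KeyError as exc:
        raise ValueError(f"animal {exc.args[0]!r} missing from pedigree") from exc
    Za = indicator_matrix(acodes, len(animals))
    cows = list(pd.unique(used["animal"]))
    cpos = {c: i for i, c in enumerate(cows)}
    Zp = indicator_matrix(np.array([cpos[c] for c in used["animal"]]), len(cows))
    terms = [
        RandomTerm("animal", Za, animals, ginv=a_inverse(pedigree)),
        RandomTerm("pe", Zp, cows),
    ]
    return LinearMixedModel(y, design, terms), used


def solve_mme(
    records: pd.DataFrame,
    cg: ContemporaryGroupAssignment,
    pedigree: PedigreeTable,
    vc: VarianceComponents,
    trait: str = "milk",
    dim_window: tuple[float, float] = (5.0, 365.0),
    inbreeding_adjusted_reliability: bool = False,
) -> MMESolution:
    """Solve the Henderson equations at known variance components.

    Prediction error variances come from the diagonal of the inverse
    coefficient matrix (exact dense inverse of the non-absorbed block; valid
    at desk scale).  Reliability r^2 = 1 - PEV / sigma_a^2, optionally with
    the (1 + F_i) sigma_a^2 denominator that accounts for inbreeding.
    """
    model, used = _genetic_model(records, cg, pedigree, trait, dim_window)
    fit = model.fit(vc.as_dict() | {"residual": vc.sigma_e2})
    return _package_solution(fit, vc, cg, used, pedigree,
                             inbreeding_adjusted_reliability)


def _package_solution(fit, vc, cg, used, pedigree, inb_adj) -> MMESolution:
    pev = pd.Series(vc.sigma_e2 * fit.diag_cinv["animal"], index=fit.u["animal"].index)
    denom = vc.sigma_a2 * (1.0 + inbreeding(pedigree)) if inb_adj else vc.sigma_a2
    rel = (1.0 - pev / denom).clip(lower=0.0, upper=1.0 - 1e-12)
    return MMESolution(
        fixed=fit.beta,
        ebv=fit.u["animal"],
        pe=fit.u["pe"],
        pev=pev,
        reliability=rel,
        vc=vc,
        fit=fit,
        cg=cg,
        records_used=used.index,
    )


def em_reml(
    records: pd.DataFrame,
    cg: ContemporaryGroupAssignment,
    pedigree: PedigreeTable,
    init_vc: VarianceComponents | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
    trait: str = "milk",
    dim_window: tuple[float, float] = (5.0, 365.0),
    compute_se: bool = False,
) -> tuple[VarianceComponents, list]:
    """EM-REML variance components for the repeatability test-day model.

    Returns the estimates and the restricted log-likelihood history
    (nondecreasing).  ``compute_se`` adds a standard error for h^2 from the
    numerically differentiated average-information (observed) matrix.
    """
    model, _ = _genetic_model(records, cg, pedigree, trait, dim_window)
    init = init_vc.as_dict() | {"residual": init_vc.sigma_e2} if init_vc else None
    fit = model.em_reml(init=init, tol=tol, max_iter=max_iter)
    se_h2 = _h2_se(model, fit.variances) if compute_se else None
    vc = VarianceComponents(
        fit.variances["animal"], fit.variances["pe"], fit.variances["residual"], se_h2
    )
    return vc, fit.history


def _h2_se(model: LinearMixedModel, variances: dict) -> float:
    """SE of h^2 by inverting the numeric Hessian of -2 log L_R."""
    names = ["animal", "pe", "residual"]
    theta = np.array([variances[n] for n in names])

    def m2(vec):
        v = dict(zip(names, vec))
        v["residual"] = vec[2]
        raw = model.solve(v, compute_cinv=False)
        return model._minus2_reml(v, raw)

    h = 1e-3 * theta
    H = np.zeros((3, 3))
    f0 = m2(theta)
    for i in range(3):
        for j in range(i, 3):
            ei, ej = np.eye(3)[i] * h[i], np.eye(3)[j] * h[j]
            if i == j:
                H[i, i] = (m2(theta + ei) - 2 * f0 + m2(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    m2(theta + ei + ej) - m2(theta + ei - ej)
                    - m2(theta - ei + ej) + m2(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = 2.0 * np.linalg.inv(H)  # var of theta from -2logL curvature
    except np.linalg.LinAlgError:
        return float("nan")
    tot = theta.sum()
    grad = np.array(
        [(tot - theta[0]) / tot**2, -theta[0] / tot**2, -theta[0] / tot**2]
    )
    var = float(grad @ cov @ grad)
    return float(np.sqrt(var)) if var > 0 else float("nan")


# ---------------------------------------------------------------------------
# scheme comparison


def compare_cg_models(
    records: pd.DataFrame,
    pedigree: PedigreeTable,
    partition: Partition,
    schemes=CG_SCHEMES,
    vc: VarianceComponents | None = None,
    trait: str = "milk",
    min_size: int = 3,
    policy: str = "drop",
    reml_tol: float = 1e-4,
    reml_max_iter: int = 100,
    compute_se: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Side-by-side genetic evaluation under the four CG schemes.

    For each scheme: CG count and occupancy, (re-estimated) variance
    components, h^2, and mean/SD of reliabilities for the whole population
    (all pedigree animals and, separately, animals with records) and for
    sires with daughter records.  Pass ``vc`` to skip REML and evaluate all
    schemes at common variance components.  Returns the comparison table
    and a dict of the full :class:`MMESolution` per scheme.
    """
    rows = []
    solutions = {}
    for scheme in schemes:
        cg = build_cg(records, partition, scheme, min_size=min_size, policy=policy)
        if vc is None:
            vc_s, _ = em_reml(
                records, cg, pedigree, tol=reml_tol, max_iter=reml_max_iter,
                trait=trait, compute_se=compute_se,
            )
        else:
            vc_s = vc
        sol = solve_mme(records, cg, pedigree, vc_s, trait=trait)
        solutions[scheme.upper()] = sol
        rel = sol.reliability
        with_rec = rel.index.isin(records.loc[sol.records_used, "animal"])
        sires = sol.sires_with_daughter_records(pedigree, records)
        occ = cg.occupancy()
        rows.append(
            {
                "scheme": scheme.upper(),
                "n_cg": cg.n_groups,
                "n_cg_raw": cg.n_groups_raw,
                "mean_cg_occupancy": float(occ.mean()),
                "min_cg_occupancy": int(occ.min()),
                "n_records": int(len(cg.cg)),
                "sigma_a2": vc_s.sigma_a2,
                "sigma_pe2": vc_s.sigma_pe2,
                "sigma_e2": vc_s.sigma_e2,
                "h2": vc_s.h2,
                "se_h2": vc_s.se_h2,
                "rel_mean_all": float(rel.mean()),
                "rel_sd_all": float(rel.std()),
                "rel_mean_recorded": float(rel[with_rec].mean()),
                "rel_sd_recorded": float(rel[with_rec].std()),
                "rel_mean_sires": float(rel.loc[sires].mean()) if sires else np.nan,
                "rel_sd_sires": float(rel.loc[sires].std()) if sires else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("scheme")
    return table, solutions
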
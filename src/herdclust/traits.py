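"""Herd-cluster trait comparison: mixed models, least-squares means, letters.

Two models compare cow traits across herd clusters (HCs).  Test-day traits
(milk, fat and protein yield and percentage, somatic cell score, fat-to-
protein ratio) use

    y = mu + breed + year-season + lactation + HC + f(DIM) + b*CA + animal + e

with a third-order Legendre regression on days in milk and an iid random
animal effect.  Female fertility traits (calving-to-first-insemination
interval CFI; first-insemination success SFI) use

    y = mu + breed + insemination month + lactation + HC + semen type
        + b*age + animal + service sire + e,

fitted as a Gaussian mixed model for CFI and by penalized quasi-likelihood
(logit link, working-variate iterations around the linear solver) for the
binary SFI.  Least-squares means are marginal means over an equal-weight
reference grid of the fixed factors with covariates at their observed
means; pairwise Student's t tests at alpha = 0.05 produce the compact
letter display.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import t as t_dist

from .clustering import Partition
from .genetics import legendre_dim
from .mixedmodel import (
    FixedDesign,
    LinearMixedModel,
    MMEFit,
    RandomTerm,
    build_fixed_design,
    indicator_matrix,
)

__all__ = [
    "scs_transform",
    "year_season",
    "TraitModelFit",
    "LsmTable",
    "fit_model1",
    "fit_model2",
    "lsmeans",
]

SEASONS = {
    12: "Dec-Feb", 1: "Dec-Feb", 2: "Dec-Feb",
    3: "Mar-May", 4: "Mar-May", 5: "Mar-May",
    6: "Jun-Aug", 7: "Jun-Aug", 8: "Jun-Aug",
    9: "Sep-Nov", 10: "Sep-Nov", 11: "Sep-Nov",
}


def scs_transform(scc) -> np.ndarray | float:
    """Somatic cell score: SCS = log2(SCC / 100 000 cells) + 3.

    SCC of 100 000 cells/mL maps to SCS 3; every doubling adds one unit.
    """
    x = np.asarray(scc, dtype=float)
    if np.any(x <= 0):
        raise ValueError("somatic cell counts must be positive")
    out = np.log2(x / 100_000.0) + 3.0
    return float(out) if np.isscalar(scc) else out


def year_season(date, with_year: bool = False) -> str:
    """Calving season: Dec-Feb, Mar-May, Jun-Aug or Sep-Nov.

    December belongs to the winter block of the *following* year, so with
    ``with_year=True`` Dec 2017, Jan 2018 and Feb 2018 share the level
    ``2018:Dec-Feb``.
    """
    d = pd.Timestamp(date)
    season = SEASONS[d.month]
    if not with_year:
        return season
    year = d.year + 1 if d.month == 12 else d.year
    return f"{year}:{season}"


@dataclass
class TraitModelFit:
    """A fitted trait-comparison model plus everything LSMs need."""

    fit: MMEFit
    model: LinearMixedModel
    data: pd.DataFrame
    trait: str
    family: str  # "gaussian" or "binomial-pql"
    factors: list[str]
    separation: list = field(default_factory=list)  # degenerate binary levels

    @property
    def design(self) -> FixedDesign:
        return self.fit.design

    @property
    def aliased(self) -> list[str]:
        return self.design.dropped


def _attach_clusters(records: pd.DataFrame, partition: Partition) -> pd.DataFrame:
    cluster_of = dict(zip(partition.herd_ids, partition.labels))
    missing = set(records["herd"]) - set(cluster_of)
    if missing:
        raise ValueError(f"herds without cluster label: {sorted(missing, key=str)}")
    out = records.copy()
    out["hc"] = records["herd"].map(cluster_of).map(lambda c: f"HC{c + 1}")
    return out


def fit_model1(
    records: pd.DataFrame,
    partition: Partition,
    trait: str,
    dim_window: tuple[float, float] = (5.0, 365.0),
    reml_tol: float = 1e-6,
    reml_max_iter: int = 200,
) -> TraitModelFit:
    """Test-day trait model with herd-cluster fixed effects.

    ``records`` needs columns animal, herd, test_date, calving_date,
    lactation, dim, calving_age, breed and the trait column (``SCS`` is
    derived from an ``scc`` column when absent).  Variance components for
    the iid animal effect are estimated by EM-REML on the same data.
    """
    data = _attach_clusters(records, partition)
    if trait == "SCS" and "SCS" not in data.columns:
        data["SCS"] = scs_transform(data["scc"].to_numpy())
    data["ys"] = pd.to_datetime(data["calving_date"]).map(
        lambda d: year_season(d, with_year=True)
    )
    leg = legendre_dim(data["dim"].to_numpy(dtype=float), order=3, window=dim_window)
    factors = ["breed", "ys", "lactation", "hc"]
    design = build_fixed_design(
        data, factors=factors, covariates=["calving_age"],
        covariate_columns={"legdim": leg[:, 1:]},
    )
    codes, animals = pd.factorize(data["animal"])
    terms = [RandomTerm("animal", indicator_matrix(codes, len(animals)), list(animals))]
    model = LinearMixedModel(data[trait].to_numpy(dtype=float), design, terms)
    fit = model.em_reml(tol=reml_tol, max_iter=reml_max_iter)
    return TraitModelFit(fit, model, data, trait, "gaussian", factors)


def fit_model2(
    records: pd.DataFrame,
    partition: Partition,
    trait: str,
    reml_tol: float = 1e-6,
    reml_max_iter: int = 200,
    pql_max_outer: int = 50,
    pql_tol: float = 1e-6,
) -> TraitModelFit:
    """Fertility model with herd-cluster fixed effects (trait CFI or SFI).

    ``records`` needs columns animal, herd, breed, lactation, insem_month,
    semen, service_sire, insem_age and the trait column.  CFI is Gaussian
    with random animal and random service sire; SFI is a logit model fitted
    by penalized quasi-likelihood with the same random structure (working
    residual variance fixed at 1).  Service sires with a single record are
    retained and shrunken, never dropped.  Herd clusters whose binary
    outcomes are all 0 or all 1 constitute complete separation on the link
    scale and are recorded in ``separation``.
    """
    trait = trait.upper()
    if trait not in ("CFI", "SFI"):
        raise ValueError("model 2 handles the traits CFI and SFI")
    data = _attach_clusters(records, partition)
    factors = ["breed", "insem_month", "lactation", "hc", "semen"]
    design = build_fixed_design(data, factors=factors, covariates=["insem_age"])
    acodes, animals = pd.factorize(data["animal"])
    scodes, sires = pd.factorize(data["service_sire"])
    terms = [
        RandomTerm("animal", indicator_matrix(acodes, len(animals)), list(animals)),
        RandomTerm("sire", indicator_matrix(scodes, len(sires)), list(sires)),
    ]
    y = data[trait].to_numpy(dtype=float)
    if trait == "CFI":
        model = LinearMixedModel(y, design, terms)
        fit = model.em_reml(tol=reml_tol, max_iter=reml_max_iter)
        return TraitModelFit(fit, model, data, trait, "gaussian", factors)
    # --- SFI: penalized quasi-likelihood on the logit scale
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("SFI must be binary 0/1")
    separation = [
        lev for lev, sub in data.groupby("hc", observed=True)[trait]
        if sub.nunique() == 1
    ]
    if separation:
        warnings.warn(
            f"complete separation: herd clusters {separation} have a "
            "constant binary outcome; their effects diverge on the logit scale",
            stacklevel=2,
        )
    mu = np.clip((y + 0.5) / 2.0, 0.02, 0.98)
    eta = logit(mu)
    vcs = {"animal": 0.1, "sire": 0.1, "residual": 1.0}
    model = fit = None
    for _ in range(pql_max_outer):
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        model = LinearMixedModel(z, design, terms, weights=w)
        fit = model.em_reml(init=vcs, fix_residual=True, tol=1e-6, max_iter=50)
        vcs = fit.variances
        raw = model.solve(vcs)
        eta_new = model.linear_predictor(raw)
        delta = float(np.max(np.abs(eta_new - eta)))
        eta = eta_new
        mu = np.clip(expit(eta), 1e-6, 1 - 1e-6)
        if delta < pql_tol:
            break
    else:
        warnings.warn("PQL outer loop did not converge", stacklevel=2)
    return TraitModelFit(fit, model, data, trait, "binomial-pql", factors,
                         separation=separation)


# ---------------------------------------------------------------------------
# least-squares means


@dataclass
class LsmTable:
    """Least-squares means with SEs, pairwise tests and a letter display.

    Levels sharing a letter do not differ at the chosen alpha.  For the
    logit-scale SFI model ``response`` holds the back-transformed means.
    """

    table: pd.DataFrame  # index = level; estimate, se, letters [, response]
    pairwise: pd.DataFrame  # p-values, symmetric
    factor: str
    alpha: float
    non_estimable: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _reference_row(design: FixedDesign, factors, target: str, level) -> tuple[np.ndarray, bool]:
    """Equal-weight reference-grid row for one level of the target factor.

    Estimability is checked against the null space of the full
    (pre-rank-reduction) design; the returned row covers the kept columns
    only, which is a valid solution representation whenever estimable.
    """
    weights = {"(Intercept)": 1.0}
    for f in factors:
        levels = design.factor_levels.get(f, [])
        if f == target:
            for lev in levels[1:]:
                weights[f"{f}[{lev}]"] = 1.0 if lev == level else 0.0
        else:
            for lev in levels[1:]:
                weights[f"{f}[{lev}]"] = 1.0 / len(levels)
    for name, mean in design.covariate_means.items():
        weights[name] = mean
    full = design.full_names or design.names
    x_full = np.array([weights.get(name, 0.0) for name in full])
    estimable = design.is_estimable(x_full)
    x = np.array([weights.get(name, 0.0) for name in design.names])
    return x, estimable


def _letters(order: list, ns: np.ndarray) -> dict:
    """Compact letter display from a boolean not-significant matrix.

    ``order`` lists levels sorted by estimate; ``ns[i, j]`` says levels i
    and j (in that order) are not significantly different.  Maximal runs of
    mutually non-significant levels each receive one letter.
    """
    m = len(order)
    runs = []
    for i in range(m):
        j = i
        while j + 1 < m and all(ns[a][b] for a in range(i, j + 2) for b in range(i, j + 2)):
            j += 1
        runs.append((i, j))
    # keep maximal runs only
    runs = [r for r in runs if not any(o[0] <= r[0] and r[1] <= o[1] and o != r for o in runs)]
    letters = {lev: "" for lev in order}
    for letter, (i, j) in zip("abcdefghijklmnopqrstuvwxyz", runs):
        for idx in range(i, j + 1):
            letters[order[idx]] += letter
    return letters


def lsmeans(
    tfit: TraitModelFit,
    factor: str = "hc",
    alpha: float = 0.05,
    adjust: str = "none",
) -> LsmTable:
    """Least-squares means of one fixed factor with pairwise comparisons.

    Marginal means over the equal-weight reference grid (all fixed-factor
    levels weighted equally, covariates at their means).  Pairwise tests
    are unadjusted Student's t tests by default; ``adjust="tukey"`` uses
    the studentized range instead.  Non-estimable levels (aliased with
    dropped design columns) are flagged, not imputed.
    """
    design = tfit.design
    if factor not in design.factor_levels:
        raise ValueError(f"{factor!r} is not a fixed factor of this model")
    levels = design.factor_levels[factor]
    beta = tfit.fit.beta.to_numpy()
    cov = tfit.fit.cov_beta
    rows, non_estimable = {}, []
    for lev in levels:
        x, ok = _reference_row(design, tfit.factors, factor, lev)
        if not ok:
            non_estimable.append(lev)
            continue
        rows[lev] = x
    ests = {lev: float(x @ beta) for lev, x in rows.items()}
    ses = {lev: float(np.sqrt(x @ cov @ x)) for lev, x in rows.items()}
    df = tfit.fit.resid_df
    levs = list(rows)
    pmat = pd.DataFrame(np.ones((len(levs), len(levs))), index=levs, columns=levs)
    for la, lb in itertools.combinations(levs, 2):
        d = rows[la] - rows[lb]
        sed = float(np.sqrt(d @ cov @ d))
        if sed == 0:
            p = 1.0
        else:
            tval = (ests[la] - ests[lb]) / sed
            if adjust == "tukey":
                from scipy.stats import studentized_range

                p = float(studentized_range.sf(abs(tval) * np.sqrt(2), len(levs), df))
            else:
                p = float(2 * t_dist.sf(abs(tval), df))
        pmat.loc[la, lb] = pmat.loc[lb, la] = p
    order = sorted(levs, key=lambda lv: ests[lv])
    ns = [[pmat.loc[a, b] >= alpha or a == b for b in order] for a in order]
    letters = _letters(order, ns)
    table = pd.DataFrame(
        {
            "estimate": pd.Series(ests),
            "se": pd.Series(ses),
            "letters": pd.Series(letters),
        }
    ).loc[levs]
    if tfit.family == "binomial-pql" and len(table):
        table["response"] = expit(table["estimate"].astype(float))
    table.index.name = factor
    return LsmTable(table, pmat, factor, alpha, non_estimable)
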
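"""Synthetic herd surveys, pedigrees, test-day and fertility records.

Every generator is seed-deterministic and returns a *truth table* next to
the data so that downstream estimators can be checked against the planted
values.  The default survey shape mirrors a small local dairy population:
30 herds in 4 clusters of sizes 13/5/1/11, characterized by 23 quantitative
and 83 qualitative variables (plus optional planted constant/duplicate
columns that the variable-editing step is expected to remove).  Genetic
data follow a repeatability test-day model: breeding values flow through a
sire pedigree, cows carry a permanent environmental effect, and
contemporary-group environments are shared at herd and/or herd-cluster
level - the latter is the explicit mechanism that makes herd-cluster
contemporary groups informative when herds are small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import Partition
from .genetics import PedigreeTable, legendre_dim
from .survey import TypedSurvey, VariableSpec

__all__ = [
    "SurveySimConfig",
    "GeneticSimConfig",
    "FertilitySimConfig",
    "simulate_survey",
    "simulate_pedigree",
    "simulate_test_days",
    "simulate_fertility",
]


# ---------------------------------------------------------------------------
# herd survey


@dataclass
class SurveySimConfig:
    """Shape and strength of the planted herd-cluster structure.

    ``separation`` shifts quantitative cluster means (in units of the noise
    SD) and tilts qualitative level probabilities: the cluster-preferred
    level gets probability tilt + (1 - tilt)/L with tilt = s/(s+1), so 0
    means no structure.  ``n_removable_*`` columns are planted constants /
    duplicates / dominant-level variables that variable editing should drop
    (defaults give the 117-column survey from which 106 survive).
    """

    cluster_sizes: tuple = (13, 5, 1, 11)
    n_quantitative: int = 23
    n_qualitative: int = 83
    separation: float = 3.0
    noise: float = 1.0
    n_removable_quantitative: int = 3
    n_removable_qualitative: int = 8
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if min(self.n_quantitative, self.n_qualitative) < 1:
            raise ValueError("need at least one variable of each kind")

    @property
    def n_herds(self) -> int:
        return int(sum(self.cluster_sizes))

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)


_QUAL_KINDS = [
    ("nominal", 3),
    ("binary_symmetric", 2),
    ("nominal", 4),
    ("ordinal", 3),
    ("binary_asymmetric", 2),
]


def simulate_survey(cfg: SurveySimConfig) -> tuple[TypedSurvey, Partition]:
    """Mixed-type herd survey with planted clusters; returns the true labels."""
    rng = np.random.default_rng(cfg.seed)
    labels = np.repeat(np.arange(cfg.n_clusters), cfg.cluster_sizes)
    n = cfg.n_herds
    herd_ids = [f"herd{i + 1:02d}" for i in range(n)]
    cols, specs = {}, []
    tilt = cfg.separation / (cfg.separation + 1.0)
    # cluster-mean patterns are random permutations of an equally spaced,
    # centered grid plus per-variable jitter: every cluster pair is equally
    # separated in expectation and no two variables are collinear.  The
    # shift is scaled so the between:within variance ratio equals the
    # qualitative tilt odds s/(s+1) : 1/(s+1) - one separation parameter,
    # same meaning for both variable kinds.
    grid = np.arange(cfg.n_clusters, dtype=float)
    grid = (grid - grid.mean()) / max(grid.std(), 1.0)
    jitter_sd = 0.5
    shift_scale = cfg.noise * np.sqrt(cfg.separation / (1.0 + jitter_sd**2))
    for q in range(cfg.n_quantitative):
        mu = shift_scale * (
            rng.permutation(grid) + rng.normal(0.0, jitter_sd, cfg.n_clusters)
        )
        cols[f"q{q + 1:03d}"] = mu[labels] + rng.normal(0.0, cfg.noise, n)
        specs.append(VariableSpec(f"q{q + 1:03d}", "quantitative"))
    for j in range(cfg.n_qualitative):
        vtype, L = _QUAL_KINDS[j % len(_QUAL_KINDS)]
        levels = tuple(str(l) for l in range(L)) if vtype != "ordinal" else ("low", "mid", "high")
        base = np.full(L, (1.0 - tilt) / L)
        vals = np.empty(n, dtype=object)
        # preferred levels spread over the clusters as evenly as the number
        # of levels allows (distinct when L >= number of clusters)
        reps = -(-cfg.n_clusters // L)
        preferred = rng.permutation(np.tile(np.arange(L), reps))[: cfg.n_clusters]
        for c in range(cfg.n_clusters):
            p = base.copy()
            p[preferred[c]] += tilt
            idx = labels == c
            vals[idx] = rng.choice(np.array(levels, dtype=object), idx.sum(), p=p)
        name = f"c{j + 1:03d}"
        if vtype.startswith("binary"):
            vals = vals.astype(int) if vtype == "binary_asymmetric" else vals
        cols[name] = vals
        specs.append(
            VariableSpec(
                name,
                vtype,
                levels=(0, 1) if vtype == "binary_asymmetric" else levels,
            )
        )
    # planted removable columns: constants, duplicates, dominant levels
    for q in range(cfg.n_removable_quantitative):
        name = f"qrm{q + 1}"
        if q == 0:
            cols[name] = np.full(n, 7.0)  # constant
        else:
            src = f"q{q:03d}"
            cols[name] = np.asarray(cols[src], dtype=float).copy()  # exact duplicate
        specs.append(VariableSpec(name, "quantitative"))
    for j in range(cfg.n_removable_qualitative):
        name = f"crm{j + 1}"
        if j % 2 == 0:
            cols[name] = np.array(["only"] * n, dtype=object)  # single level
        else:
            v = np.array(["major"] * n, dtype=object)
            v[j % n] = "minor"  # dominant share (n-1)/n
            cols[name] = v
        specs.append(VariableSpec(name, "nominal"))
    values = pd.DataFrame(cols, index=herd_ids)
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values = values.mask(mask)
    return TypedSurvey(values, specs), Partition(herd_ids, labels)


# ---------------------------------------------------------------------------
# pedigree and test-day records


@dataclass
class GeneticSimConfig:
    """Population and variance structure of the test-day simulation.

    Cows descend from ``n_sires`` unrelated sires (dams unknown), giving
    the paternal half-sib families that make sigma_a2 and sigma_pe2
    separable.  Records follow y = mu + fixed effects + CG environment
    + lactation curve + BV + PE + e.  The CG environment is
    cluster x test-month (SD ``cluster_env_sd``) plus herd x test-day
    (SD ``herd_env_sd``): a large cluster share with sparse herds is
    exactly the situation in which herd-cluster contemporary groups pay
    off.  Default variances give h^2 = 0.30 and repeatability 0.50
    (sigma_a2 = 3, sigma_pe2 = 2, sigma_e2 = 5).
    """

    n_sires: int = 40
    daughters_per_sire: int = 25
    n_herds: int = 40
    n_clusters: int = 4
    records_per_cow: int = 5
    mu: float = 20.0
    sigma_a2: float = 3.0
    sigma_pe2: float = 2.0
    sigma_e2: float = 5.0
    cluster_env_sd: float = 2.0
    herd_env_sd: float = 0.5
    breed_effect: float = 4.0
    lactation_effects: tuple = (0.0, 1.5, 2.0)
    curve_coeffs: tuple = (0.0, -2.0, 1.0, -0.3)  # Legendre P0..P3 loadings
    calving_age_slope: float = 0.05
    dim_window: tuple = (5.0, 365.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.sigma_a2, self.sigma_pe2, self.sigma_e2) < 0:
            raise ValueError("variances must be nonnegative")
        if self.n_sires < 1 or self.daughters_per_sire < 1:
            raise ValueError("empty pedigree configuration")

    @property
    def n_cows(self) -> int:
        return self.n_sires * self.daughters_per_sire


def simulate_pedigree(cfg: GeneticSimConfig) -> tuple[PedigreeTable, pd.Series]:
    """Sire pedigree plus true breeding values.

    Founder (sire) BVs are N(0, sigma_a2); each daughter receives half her
    sire's BV (the unknown dam contributes 0 on average) plus Mendelian
    sampling N(0, 3/4 sigma_a2), so daughter BVs also have variance
    sigma_a2 and the daughter-on-sire regression is 1/2.
    """
    rng = np.random.default_rng(cfg.seed)
    sires = [f"S{i + 1:03d}" for i in range(cfg.n_sires)]
    cows = [f"C{i + 1:05d}" for i in range(cfg.n_cows)]
    sire_of = np.repeat(np.arange(cfg.n_sires), cfg.daughters_per_sire)
    bv_s = rng.normal(0.0, np.sqrt(cfg.sigma_a2), cfg.n_sires)
    bv_c = 0.5 * bv_s[sire_of] + rng.normal(
        0.0, np.sqrt(0.75 * cfg.sigma_a2), cfg.n_cows
    )
    ped = pd.DataFrame(
        {
            "animal": sires + cows,
            "sire": [np.nan] * cfg.n_sires + [sires[s] for s in sire_of],
            "dam": np.nan,
        }
    )
    bv = pd.Series(np.concatenate([bv_s, bv_c]), index=sires + cows, name="true_bv")
    return PedigreeTable(ped), bv


def _herd_partition(cfg: GeneticSimConfig) -> Partition:
    herds = [f"h{i + 1:03d}" for i in range(cfg.n_herds)]
    labels = np.arange(cfg.n_herds) % cfg.n_clusters
    return Partition(herds, labels)


def simulate_test_days(
    pedigree: PedigreeTable,
    bv: pd.Series,
    cfg: GeneticSimConfig,
    partition: Partition | None = None,
) -> tuple[pd.DataFrame, Partition, dict]:
    """Test-day records for every cow of the pedigree.

    Cows are spread round-robin over ``n_herds`` herds (themselves assigned
    round-robin to clusters).  Each herd has one milk recording day per
    month; a cow's records sit on her herd's schedule at roughly monthly
    DIM intervals.  Returns (records, herd partition, truth) where truth
    holds the planted BV/PE/CG effects.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    part = partition if partition is not None else _herd_partition(cfg)
    herds = part.herd_ids
    cows = [a for a in pedigree.animals if str(a).startswith("C")]
    n_c = len(cows)
    herd_of = np.arange(n_c) % len(herds)
    pe = rng.normal(0.0, np.sqrt(cfg.sigma_pe2), n_c)
    herd_day = {h: int(rng.integers(1, 28)) for h in herds}
    cluster_month_eff: dict = {}
    herd_date_eff: dict = {}
    rows = []
    for ci, cow in enumerate(cows):
        h = herds[herd_of[ci]]
        cl = part.labels[herd_of[ci]]
        lact = int(rng.integers(1, 4))
        calv_month = int(rng.integers(0, 12))
        calving = pd.Timestamp("2017-01-15") + pd.DateOffset(months=calv_month)
        ca = float(np.round(22 + 12 * (lact - 1) + rng.normal(0, 2), 1))
        # mostly breed-pure clusters with some mixed herds, so that the breed
        # effect stays estimable next to the contemporary-group effects
        p_hf = 0.9 if cl == part.k - 1 else 0.1
        breed = "HF" if rng.random() < p_hf else "DSN"
        for rec in range(cfg.records_per_cow):
            month_offset = 1 + rec * max(1, 11 // max(cfg.records_per_cow, 1))
            test = (calving + pd.DateOffset(months=month_offset)).replace(
                day=herd_day[h]
            )
            dim = (test - calving).days
            if not cfg.dim_window[0] <= dim <= cfg.dim_window[1]:
                dim = float(np.clip(dim, *cfg.dim_window))
            key_cm = (cl, test.strftime("%Y-%m"))
            if key_cm not in cluster_month_eff:
                cluster_month_eff[key_cm] = rng.normal(0.0, cfg.cluster_env_sd)
            key_hd = (h, test.strftime("%Y-%m-%d"))
            if key_hd not in herd_date_eff:
                herd_date_eff[key_hd] = rng.normal(0.0, cfg.herd_env_sd)
            leg = legendre_dim(dim, order=3, window=cfg.dim_window)
            y = (
                cfg.mu
                + (cfg.breed_effect if breed == "HF" else 0.0)
                + cfg.lactation_effects[lact - 1]
                + cfg.calving_age_slope * (ca - 30.0)
                + float(np.dot(cfg.curve_coeffs, leg))
                + cluster_month_eff[key_cm]
                + herd_date_eff[key_hd]
                + bv[cow]
                + pe[ci]
                + rng.normal(0.0, np.sqrt(cfg.sigma_e2))
            )
            rows.append(
                {
                    "animal": cow,
                    "herd": h,
                    "breed": breed,
                    "test_date": test.date().isoformat(),
                    "calving_date": calving.date().isoformat(),
                    "lactation": lact,
                    "dim": float(dim),
                    "calving_age": ca,
                    "milk": y,
                }
            )
    records = pd.DataFrame(rows)
    truth = {
        "bv": bv,
        "pe": pd.Series(pe, index=cows, name="true_pe"),
        "cluster_month_effects": cluster_month_eff,
        "herd_date_effects": herd_date_eff,
    }
    return records, part, truth


# ---------------------------------------------------------------------------
# fertility records


@dataclass
class FertilitySimConfig:
    """Planted structure of the fertility traits CFI (days) and SFI (0/1)."""

    n_cows: int = 1000
    n_herds: int = 20
    n_clusters: int = 4
    n_service_sires: int = 25
    cfi_mu: float = 80.0
    cfi_cluster_shift: tuple = (0.0, 20.0, -5.0, 5.0)
    sfi_logit_mu: float = 0.3
    sfi_cluster_shift: tuple = (0.0, -0.5, 0.3, -0.8)
    breed_effect_cfi: float = 5.0
    breed_effect_sfi: float = -0.4
    sigma_animal_cfi: float = 8.0  # SDs, not variances
    sigma_sire_cfi: float = 5.0
    sigma_e_cfi: float = 15.0
    sigma_animal_sfi: float = 0.3
    sigma_sire_sfi: float = 0.3
    repeat_fraction: float = 0.35  # share of cows with a second lactation record
    seed: int = 0

    def __post_init__(self):
        if len(self.cfi_cluster_shift) != self.n_clusters:
            raise ValueError("one CFI shift per cluster required")
        if len(self.sfi_cluster_shift) != self.n_clusters:
            raise ValueError("one SFI shift per cluster required")


def simulate_fertility(cfg: FertilitySimConfig) -> tuple[pd.DataFrame, Partition, dict]:
    """Fertility records (one per cow plus repeats for a configurable share
    of cows, mirroring repeated lactations); returns (records, partition,
    truth).  Repeated records are what separates the cow effect from the
    residual."""
    rng = np.random.default_rng(cfg.seed + 2)
    herds = [f"h{i + 1:03d}" for i in range(cfg.n_herds)]
    labels = np.arange(cfg.n_herds) % cfg.n_clusters
    part = Partition(herds, labels)
    herd_of = rng.integers(0, cfg.n_herds, cfg.n_cows)
    cl = labels[herd_of]
    # mostly breed-pure clusters, with enough mixing for estimability
    p_hf = np.where(cl == cfg.n_clusters - 1, 0.9, 0.1)
    breed = np.where(rng.random(cfg.n_cows) < p_hf, "HF", "DSN")
    u_cfi = rng.normal(0, cfg.sigma_animal_cfi, cfg.n_cows)
    s_cfi = rng.normal(0, cfg.sigma_sire_cfi, cfg.n_service_sires)
    u_sfi = rng.normal(0, cfg.sigma_animal_sfi, cfg.n_cows)
    s_sfi = rng.normal(0, cfg.sigma_sire_sfi, cfg.n_service_sires)
    repeats = rng.random(cfg.n_cows) < cfg.repeat_fraction
    from scipy.special import expit

    rows = []
    for i in range(cfg.n_cows):
        first_lact = int(rng.integers(1, 3))
        for r in range(2 if repeats[i] else 1):
            lact = min(first_lact + r, 3)
            month = int(rng.integers(1, 13))
            semen = rng.choice(["fresh", "frozen", "natural"], p=[0.2, 0.6, 0.2])
            sire = int(rng.integers(0, cfg.n_service_sires))
            age = 24 + 12 * (lact - 1) + rng.normal(0, 2)
            cfi = (
                cfg.cfi_mu
                + cfg.cfi_cluster_shift[cl[i]]
                + (cfg.breed_effect_cfi if breed[i] == "HF" else 0.0)
                + 1.5 * (lact - 1)
                + u_cfi[i]
                + s_cfi[sire]
                + rng.normal(0, cfg.sigma_e_cfi)
            )
            eta = (
                cfg.sfi_logit_mu
                + cfg.sfi_cluster_shift[cl[i]]
                + (cfg.breed_effect_sfi if breed[i] == "HF" else 0.0)
                + u_sfi[i]
                + s_sfi[sire]
            )
            rows.append(
                {
                    "animal": f"F{i + 1:05d}",
                    "herd": herds[herd_of[i]],
                    "breed": breed[i],
                    "lactation": lact,
                    "insem_month": month,
                    "semen": semen,
                    "service_sire": f"SS{sire + 1:03d}",
                    "insem_age": round(float(age), 1),
                    "CFI": round(float(max(cfi, 20.0)), 1),
                    "SFI": int(rng.random() < expit(eta)),
                }
            )
    records = pd.DataFrame(rows)
    animals = [f"F{i + 1:05d}" for i in range(cfg.n_cows)]
    ss = [f"SS{i + 1:03d}" for i in range(cfg.n_service_sires)]
    truth = {
        "animal_cfi": pd.Series(u_cfi, index=animals),
        "sire_cfi": pd.Series(s_cfi, index=ss),
        "sire_sfi": pd.Series(s_sfi, index=ss),
    }
    return records, part, truth
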
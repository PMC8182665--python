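"""Typed herd surveys, variable editing and the mixed-data Gower dissimilarity.

A herd survey is a small table (one row per herd) whose columns mix
quantitative measurements with nominal, ordinal and binary answers.  The
variable type of every column is declared explicitly in a
:class:`VariableSpec`; nothing is ever inferred from the data.  The Gower
coefficient, with the customary modifications for standardized quantitative
variables and asymmetric binaries, turns such a table into a herd x herd
dissimilarity matrix bounded by [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "TypedSurvey",
    "DissimilarityMatrix",
    "VTYPES",
    "z_transform",
    "edit_variables",
    "gower_matrix",
    "read_survey",
    "read_variable_specs",
]

VTYPES = (
    "quantitative",
    "nominal",
    "ordinal",
    "binary_symmetric",
    "binary_asymmetric",
)

QUALITATIVE_VTYPES = ("nominal", "ordinal", "binary_symmetric", "binary_asymmetric")


class DegenerateVariableError(ValueError):
    """A variable has no usable variation (e.g. constant column)."""


class UndefinedDistanceError(ValueError):
    """Two herds share no observed, comparable variable."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one survey variable.

    Parameters
    ----------
    name
        Column name, unique within a survey.
    vtype
        One of ``quantitative``, ``nominal``, ``ordinal``,
        ``binary_symmetric`` or ``binary_asymmetric``.
    levels
        Ordered category labels.  Required for ordinal variables (the order
        defines the ranks); optional for nominal/binary ones.  For asymmetric
        binaries the *first* level is the "absent" state whose joint
        occurrence is ignored by the Gower coefficient.
    weight
        Nonnegative Gower weight (default 1).
    """

    name: str
    vtype: str
    levels: tuple | None = None
    weight: float = 1.0

    def __post_init__(self):
        if self.vtype not in VTYPES:
            raise ValueError(f"unknown variable type {self.vtype!r} for {self.name!r}")
        if self.weight < 0:
            raise ValueError(f"negative weight for {self.name!r}")
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(self.levels))
        if self.vtype == "ordinal":
            if self.levels is None or len(self.levels) < 2:
                raise ValueError(f"ordinal variable {self.name!r} needs >=2 ordered levels")
        if self.vtype.startswith("binary") and self.levels is not None and len(self.levels) != 2:
            raise ValueError(f"binary variable {self.name!r} must have exactly 2 levels")

    @property
    def is_quantitative(self) -> bool:
        return self.vtype == "quantitative"


@dataclass
class TypedSurvey:
    """Herd x variable table plus one :class:`VariableSpec` per column."""

    values: pd.DataFrame
    specs: list[VariableSpec] = field(default_factory=list)

    def __post_init__(self):
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in specs")
        if list(self.values.columns) != names:
            raise ValueError("survey columns do not match variable specs")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate herd ids")
        for s in self.specs:
            if s.is_quantitative and not pd.api.types.is_numeric_dtype(self.values[s.name]):
                raise TypeError(f"quantitative column {s.name!r} is not numeric")

    @property
    def herd_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_herds(self) -> int:
        return len(self.values)

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def select(self, names) -> "TypedSurvey":
        names = list(names)
        return TypedSurvey(self.values[names].copy(), [self.spec(n) for n in names])

    def standardized(self) -> "TypedSurvey":
        """Return a copy with every quantitative column z-transformed."""
        vals = self.values.copy()
        for s in self.specs:
            if s.is_quantitative:
                vals[s.name] = z_transform(vals[s.name].to_numpy(dtype=float))
        return TypedSurvey(vals, list(self.specs))


@dataclass
class DissimilarityMatrix:
    """Symmetric herd x herd Gower dissimilarity, entries in [0, 1]."""

    herd_ids: list
    D: np.ndarray

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.herd_ids)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape does not match herd ids")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValueError("dissimilarity matrix is not symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("dissimilarity diagonal must be exactly 0")
        finite = self.D[np.isfinite(self.D)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("dissimilarities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.herd_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.herd_ids, columns=self.herd_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def z_transform(column) -> np.ndarray:
    """Standardize a quantitative column to mean 0 and sample variance 1.

    Missing entries (NaN) are ignored when estimating the moments and stay
    missing in the output.  A column with fewer than two observed values or
    zero variance raises :class:`DegenerateVariableError`.
    """
    x = np.asarray(column, dtype=float)
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise DegenerateVariableError("need >=2 non-missing values to standardize")
    sd = np.std(x[obs], ddof=1)
    if sd == 0:
        raise DegenerateVariableError("zero-variance column cannot be standardized")
    out = x.copy()
    out[obs] = (x[obs] - np.mean(x[obs])) / sd
    return out


def edit_variables(
    survey: TypedSurvey,
    *,
    min_level_count: int = 2,
    max_dominant_share: float = 0.95,
    max_abs_assoc: float = 0.95,
) -> tuple[TypedSurvey, list[dict]]:
    """Drop variables with limited variation or near-duplicate information.

    Qualitative variables are removed when fewer than ``min_level_count``
    levels are observed, or when the most frequent level covers at least
    ``max_dominant_share`` of the herds.  Quantitative variables are removed
    when constant, and for every pair with \\|Pearson r\\| > ``max_abs_assoc``
    the later column (survey order) is removed.  Returns the edited survey
    and a removal log with one entry ``{"name", "reason"}`` per drop.
    """
    log: list[dict] = []
    keep: list[str] = []
    quant_kept: list[str] = []
    for s in survey.specs:
        col = survey.values[s.name]
        if s.is_quantitative:
            x = col.to_numpy(dtype=float)
            obs = x[~np.isnan(x)]
            if obs.size < 2 or np.std(obs, ddof=1) == 0:
                log.append({"name": s.name, "reason": "zero variance"})
                continue
            drop = False
            for other in quant_kept:
                y = survey.values[other].to_numpy(dtype=float)
                both = ~np.isnan(x) & ~np.isnan(y)
                if both.sum() >= 3 and np.std(x[both]) > 0 and np.std(y[both]) > 0:
                    r = np.corrcoef(x[both], y[both])[0, 1]
                    if abs(r) > max_abs_assoc:
                        log.append(
                            {"name": s.name, "reason": f"|r|={abs(r):.3f} with {other}"}
                        )
                        drop = True
                        break
            if drop:
                continue
            quant_kept.append(s.name)
        else:
            counts = col.dropna().value_counts()
            if len(counts) < min_level_count:
                log.append({"name": s.name, "reason": "fewer than 2 observed levels"})
                continue
            share = counts.iloc[0] / counts.sum()
            if share >= max_dominant_share:
                log.append(
                    {"name": s.name, "reason": f"dominant level share {share:.3f}"}
                )
                continue
        keep.append(s.name)
    if not keep:
        warnings.warn("variable editing removed every column", stacklevel=2)
        return TypedSurvey(survey.values[[]], []), log
    return survey.select(keep), log


def _column_contributions(survey: TypedSurvey, s: VariableSpec):
    """Per-pair (d_ijk, delta_ijk) matrices for one variable."""
    col = survey.values[s.name]
    n = survey.n_herds
    if s.is_quantitative or s.vtype == "ordinal":
        if s.vtype == "ordinal":
            ranks = col.map({lev: i for i, lev in enumerate(s.levels)}).to_numpy(dtype=float)
            span = len(s.levels) - 1
            x = ranks / span  # (r-1)/(max_r-1) on 0-based ranks
        else:
            x = col.to_numpy(dtype=float)
        obs = ~np.isnan(x)
        delta = np.outer(obs, obs).astype(float)
        d = np.zeros((n, n))
        if obs.sum() >= 2:
            rng = np.nanmax(x) - np.nanmin(x)
            if rng > 0:
                xi = np.where(obs, x, 0.0)
                d = np.abs(xi[:, None] - xi[None, :]) / rng
        return d, delta
    # categorical kinds
    vals = col.to_numpy(dtype=object)
    obs = np.array([not pd.isna(v) for v in vals])
    delta = np.outer(obs, obs).astype(float)
    codes = pd.factorize(col, use_na_sentinel=True)[0]
    d = (codes[:, None] != codes[None, :]).astype(float)
    d[~np.outer(obs, obs)] = 0.0
    if s.vtype == "binary_asymmetric":
        absent = _absent_mask(col, s)
        joint_absent = np.outer(absent, absent)
        delta[joint_absent] = 0.0
    return d, delta


def _absent_mask(col: pd.Series, s: VariableSpec) -> np.ndarray:
    """Which herds are in the 'absent' state of an asymmetric binary."""
    if s.levels is not None:
        absent_level = s.levels[0]
    else:
        observed = sorted(col.dropna().unique(), key=str)
        if not observed:
            return np.zeros(len(col), dtype=bool)
        absent_level = 0 if 0 in observed else observed[0]
    return (col == absent_level).to_numpy()


def gower_matrix(survey: TypedSurvey) -> DissimilarityMatrix:
    """Mixed-data Gower dissimilarity matrix.

    d(i,j) = sum_k w_k delta_ijk d_ijk / sum_k w_k delta_ijk, where
    quantitative (and rank-normalized ordinal) variables contribute
    range-normalized absolute differences, nominal and symmetric binary
    variables contribute simple mismatch, and asymmetric binaries skip
    joint-absence pairs (delta = 0).  delta is also 0 whenever either value
    is missing.  A pair of herds with no comparable variable at all raises
    :class:`UndefinedDistanceError`.
    """
    n = survey.n_herds
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for s in survey.specs:
        if s.weight == 0:
            continue
        d, delta = _column_contributions(survey, s)
        num += s.weight * delta * d
        den += s.weight * delta
    off = ~np.eye(n, dtype=bool)
    if np.any(den[off] == 0):
        i, j = np.argwhere((den == 0) & off)[0]
        raise UndefinedDistanceError(
            f"herds {survey.herd_ids[i]!r} and {survey.herd_ids[j]!r} share no comparable variable"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)  # exact symmetry against float noise
    return DissimilarityMatrix(survey.herd_ids, np.clip(D, 0.0, 1.0))


# ---------------------------------------------------------------------------
# I/O


def read_variable_specs(path) -> list[VariableSpec]:
    """Read variable declarations from a YAML or CSV sidecar file.

    YAML: a list of mappings with keys name, vtype, levels (optional),
    weight (optional).  CSV: columns name,vtype,levels,weight with levels
    '|'-separated.
    """
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return [
            VariableSpec(
                name=e["name"],
                vtype=e["vtype"],
                levels=tuple(e["levels"]) if e.get("levels") else None,
                weight=float(e.get("weight", 1.0)),
            )
            for e in raw
        ]
    tab = pd.read_csv(path)
    specs = []
    for _, row in tab.iterrows():
        levels = None
        if "levels" in row and isinstance(row["levels"], str) and row["levels"]:
            levels = tuple(row["levels"].split("|"))
        weight = float(row["weight"]) if "weight" in row and pd.notna(row.get("weight")) else 1.0
        specs.append(VariableSpec(row["name"], row["vtype"], levels, weight))
    return specs


def write_variable_specs(specs: list[VariableSpec], path) -> None:
    entries = []
    for s in specs:
        e = {"name": s.name, "vtype": s.vtype, "weight": float(s.weight)}
        if s.levels is not None:
            e["levels"] = list(s.levels)
        entries.append(e)
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def read_survey(values_path, specs_path) -> TypedSurvey:
    """Load a survey from a CSV (first column = herd id) plus a spec sidecar."""
    specs = read_variable_specs(specs_path)
    vals = pd.read_csv(values_path, index_col=0)
    vals = vals[[s.name for s in specs]]
    for s in specs:
        if s.is_quantitative:
            vals[s.name] = pd.to_numeric(vals[s.name])
    return TypedSurvey(vals, specs)
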
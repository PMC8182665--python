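"""Henderson mixed-model equations with EM-REML variance components.

The engine behind both the herd-cluster trait comparisons and the pedigree
genetic evaluations.  A model is

    y = X b + sum_j Z_j u_j + e,   u_j ~ N(0, sigma_j^2 G_j),  e ~ N(0, sigma_e^2 R)

with R diagonal (identity, or 1/weights for quasi-likelihood working
variates) and G_j either the identity or a pedigree relationship matrix
supplied through its sparse inverse.  Solving uses absorption: random terms
whose coefficient block is diagonal (iid effects with one level per record
column, e.g. permanent environment or service sire) are absorbed
analytically, so the dense system that is factorized only contains the
fixed effects plus correlated random terms such as the additive genetic
effect.  The diagonal of the inverse coefficient matrix - needed for EM
traces, prediction error variances and standard errors - is recovered from
the same factorization.

Variance components are estimated by EM-REML; each update is the classical

    sigma_j^2 <- (u_j' G_j^-1 u_j + sigma_e^2 tr(G_j^-1 C^jj)) / q_j
    sigma_e^2 <- (y'R^-1 y - sol' rhs) / (n - rank(X))

which keeps the restricted likelihood nondecreasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

__all__ = [
    "RandomTerm",
    "MMEFit",
    "LinearMixedModel",
    "FixedDesign",
    "build_fixed_design",
    "indicator_matrix",
]


# ---------------------------------------------------------------------------
# design construction


def indicator_matrix(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    """Sparse 0/1 incidence matrix from integer level codes."""
    n = len(codes)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


@dataclass
class FixedDesign:
    """Dense fixed-effect design matrix with named, full-rank columns.

    When columns had to be dropped for rank, ``null_basis`` spans the null
    space of the original (rank-deficient) design over ``full_names``; a
    linear combination of effects is estimable iff it is orthogonal to it.
    """

    X: np.ndarray
    names: list[str]
    dropped: list[str] = field(default_factory=list)  # aliased columns removed
    factor_levels: dict = field(default_factory=dict)  # factor -> ordered levels
    covariate_means: dict = field(default_factory=dict)
    full_names: list[str] = field(default_factory=list)
    null_basis: np.ndarray | None = None  # (n_full, n_null) or None

    @property
    def rank(self) -> int:
        return self.X.shape[1]

    def is_estimable(self, x_full: np.ndarray, tol: float = 1e-8) -> bool:
        if self.null_basis is None:
            return True
        return bool(np.max(np.abs(x_full @ self.null_basis)) < tol * max(
            1.0, np.linalg.norm(x_full)
        ))


def build_fixed_design(
    data: pd.DataFrame,
    factors: list[str],
    covariates: list[str] = (),
    covariate_columns: dict | None = None,
) -> FixedDesign:
    """Intercept + treatment-coded factors + covariates, reduced to full rank.

    The first level of every factor is the reference.  Columns that remain
    linearly dependent after treatment coding (confounded factor levels) are
    removed by pivoted QR and reported in ``dropped`` so the caller can name
    the aliased levels instead of silently producing garbage.
    ``covariate_columns`` may map a name to a precomputed (n x q) array,
    e.g. a Legendre polynomial basis.
    """
    n = len(data)
    if n == 0:
        raise ValueError("cannot build a design matrix from zero records")
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    factor_levels = {}
    for f in factors:
        codes, levels = pd.factorize(data[f], sort=True)
        if (codes < 0).any():
            raise ValueError(f"missing values in factor {f!r}")
        factor_levels[f] = list(levels)
        if len(levels) < 2:
            warnings.warn(f"factor {f!r} has a single level; dropped", stacklevel=2)
            continue
        for j, lev in enumerate(levels[1:], start=1):
            cols.append((codes == j).astype(float))
            names.append(f"{f}[{lev}]")
    covariate_means = {}
    for c in covariates:
        x = data[c].to_numpy(dtype=float)
        covariate_means[c] = float(x.mean())
        cols.append(x)
        names.append(c)
    for cname, arr in (covariate_columns or {}).items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if arr.shape[0] != n:
            arr = arr.T
        for j in range(arr.shape[1]):
            cols.append(arr[:, j])
            names.append(f"{cname}{j}")
            covariate_means[f"{cname}{j}"] = float(arr[:, j].mean())
    X = np.column_stack(cols)
    # order-preserving rank detection: in an unpivoted QR a small diagonal
    # entry of R marks a column (nearly) dependent on *earlier* columns, so
    # the intercept and leading factors always win over later aliases
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    colnorm = np.linalg.norm(X, axis=0)
    tol = max(X.shape) * np.finfo(float).eps
    keep = np.flatnonzero(diag > tol * np.maximum(colnorm, 1.0) * 100)
    dropped = [names[i] for i in range(X.shape[1]) if i not in set(keep)]
    null_basis = None
    if dropped:
        warnings.warn(f"aliased fixed-effect columns dropped: {dropped}", stacklevel=2)
        _, sv, Vt = np.linalg.svd(X, full_matrices=True)
        null_basis = Vt[len(keep):].T  # columns span the design null space
    return FixedDesign(
        X[:, keep],
        [names[i] for i in keep],
        dropped,
        factor_levels,
        covariate_means,
        full_names=names,
        null_basis=null_basis,
    )


# ---------------------------------------------------------------------------
# random terms and the solver


@dataclass
class RandomTerm:
    """One random effect: u ~ N(0, sigma^2 G), G given through its inverse.

    ``ginv=None`` means G = I.  The term is absorbed analytically when
    G = I and Z'Z is diagonal (each record touches one level).
    """

    name: str
    Z: sp.csr_matrix
    levels: list
    ginv: sp.csr_matrix | None = None

    def __post_init__(self):
        self.Z = sp.csr_matrix(self.Z)
        if self.ginv is not None:
            self.ginv = sp.csr_matrix(self.ginv)
            if self.ginv.shape != (self.q, self.q):
                raise ValueError(f"G-inverse of {self.name!r} has wrong shape")

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def absorbable(self) -> bool:
        if self.ginv is not None:
            return False
        ZtZ = (self.Z.T @ self.Z).tocoo()
        return bool(np.all(ZtZ.row == ZtZ.col))


@dataclass
class MMEFit:
    """Solutions and curvature of one mixed-model solve."""

    beta: pd.Series
    u: dict  # term name -> pd.Series of BLUPs
    variances: dict  # term name -> sigma^2, plus "residual"
    diag_cinv: dict  # term name -> diagonal of C^-1 block (lambda-form)
    cov_beta: np.ndarray  # sigma_e^2 * fixed block of C^-1
    sigma_e2: float
    n_obs: int
    rank_x: int
    minus2_reml: float
    design: FixedDesign
    converged: bool = True
    history: list = field(default_factory=list)

    @property
    def resid_df(self) -> int:
        return self.n_obs - self.rank_x

    def term_cinv_block(self, name: str):
        return self.diag_cinv[name]


class LinearMixedModel:
    """A Gaussian mixed model ready for solving / EM-REML.

    Parameters
    ----------
    y : response vector.
    design : :class:`FixedDesign` (already full rank).
    random_terms : list of :class:`RandomTerm`.
    weights : optional per-record precisions (R = diag(1/weights)); used for
        penalized quasi-likelihood working variates.
    """

    def __init__(self, y, design: FixedDesign, random_terms: list[RandomTerm],
                 weights=None):
        self.y = np.asarray(y, dtype=float)
        self.design = design
        self.terms = list(random_terms)
        n = len(self.y)
        if design.X.shape[0] != n:
            raise ValueError("design and response lengths differ")
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        # absorb the largest diagonal-block term; absorbing several at once
        # would be wrong because their cross-products are not diagonal
        absorbable = [t for t in self.terms if t.absorbable]
        self._absorbed = (
            [max(absorbable, key=lambda t: t.q)] if absorbable else []
        )
        absorbed_ids = {id(t) for t in self._absorbed}
        self._kept = [t for t in self.terms if id(t) not in absorbed_ids]
        w = np.ones(n) if self.weights is None else self.weights
        Wmat_parts = [sp.csr_matrix(design.X)] + [t.Z for t in self._kept]
        self._W = sp.hstack(Wmat_parts, format="csr")
        self._V = (
            sp.hstack([t.Z for t in self._absorbed], format="csr")
            if self._absorbed
            else None
        )
        Rw = sp.diags(w)
        self._WtW = (self._W.T @ Rw @ self._W).toarray()
        self._Wty = self._W.T @ (w * self.y)
        if self._V is not None:
            self._VtV_diag = np.asarray((self._V.T @ Rw @ self._V).diagonal())
            self._WtV = (self._W.T @ Rw @ self._V).toarray()
            self._Vty = self._V.T @ (w * self.y)
        self._yty = float(self.y @ (w * self.y))
        self.p = design.rank
        self._kept_slices = []
        off = self.p
        for t in self._kept:
            self._kept_slices.append((t, slice(off, off + t.q)))
            off += t.q
        self._abs_slices = []
        off = 0
        for t in self._absorbed:
            self._abs_slices.append((t, slice(off, off + t.q)))
            off += t.q

    # -- core factorization ------------------------------------------------

    def _assemble(self, variances: dict, sigma_e2: float):
        """Schur complement S over (fixed + kept random), absorbed diagonal d."""
        S = self._WtW.copy()
        for t, slc in self._kept_slices:
            lam = sigma_e2 / variances[t.name]
            if t.ginv is None:
                S[slc, slc] += lam * np.eye(t.q)
            else:
                S[slc, slc] += lam * t.ginv.toarray()
        rhs = self._Wty.copy()
        d = None
        if self._V is not None:
            d = self._VtV_diag.copy()
            for t, slc in self._abs_slices:
                d[slc] += sigma_e2 / variances[t.name]
            WVd = self._WtV / d
            S -= WVd @ self._WtV.T
            rhs = rhs - WVd @ self._Vty
        return S, rhs, d

    def solve(self, variances: dict, compute_cinv: bool = True) -> dict:
        """Solve the MME at fixed variance components.

        Returns raw arrays: solutions, diagonals of C^-1 blocks, logdet.
        """
        sigma_e2 = variances["residual"]
        S, rhs, d = self._assemble(variances, sigma_e2)
        try:
            cf = sla.cho_factor(S, lower=True, check_finite=False)
        except sla.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular mixed-model equations (aliasing after constraints?)"
            ) from exc
        sol_keep = sla.cho_solve(cf, rhs, check_finite=False)
        out = {"sol_keep": sol_keep, "d": d, "sigma_e2": sigma_e2}
        out["logdet_C"] = 2.0 * np.log(np.diag(cf[0])).sum() + (
            float(np.log(d).sum()) if d is not None else 0.0
        )
        if self._V is not None:
            sol_abs = (self._Vty - self._WtV.T @ sol_keep) / d
            out["sol_abs"] = sol_abs
        if compute_cinv:
            Sinv = sla.cho_solve(cf, np.eye(S.shape[0]), check_finite=False)
            out["Sinv"] = Sinv
            if self._V is not None:
                WVd = self._WtV / d
                M2 = Sinv @ WVd
                out["diag_abs"] = 1.0 / d + np.einsum("ij,ij->j", WVd, M2)
        return out

    def linear_predictor(self, raw) -> np.ndarray:
        """X b + sum_j Z_j u_j at the solutions of one raw solve."""
        eta = self._W @ raw["sol_keep"]
        if self._V is not None:
            eta = eta + self._V @ raw["sol_abs"]
        return np.asarray(eta)

    def _sol_rhs_product(self, raw) -> float:
        tot = float(raw["sol_keep"] @ self._Wty)
        if self._V is not None:
            tot += float(raw["sol_abs"] @ self._Vty)
        return tot

    def _minus2_reml(self, variances: dict, raw) -> float:
        n = len(self.y)
        m = self._WtW.shape[0] + (len(raw["d"]) if raw["d"] is not None else 0)
        sigma_e2 = variances["residual"]
        ypy = (self._yty - self._sol_rhs_product(raw)) / sigma_e2
        val = (n - m) * np.log(sigma_e2) + raw["logdet_C"] + ypy
        for t in self.terms:
            val += t.q * np.log(variances[t.name])
        if self.weights is not None:
            val += float(np.log(1.0 / self.weights).sum())
        return float(val)

    # -- public fitting API ------------------------------------------------

    def fit(self, variances: dict) -> MMEFit:
        """BLUE/BLUP solutions at known variance components."""
        raw = self.solve(variances)
        return self._package(variances, raw)

    def em_reml(
        self,
        init: dict | None = None,
        tol: float = 1e-6,
        max_iter: int = 200,
        fix_residual: bool = False,
        accelerate: bool = True,
        verbose: bool = False,
    ) -> MMEFit:
        """EM-REML estimation of all variance components.

        ``init`` maps term names (and "residual") to starting values; the
        default splits the phenotypic variance equally.  Components are
        floored at 1e-8 x var(y) when an update collapses to zero.
        Iteration stops when the largest relative component change drops
        below ``tol``.  With ``accelerate`` each EM step is extrapolated
        along the update direction with an adaptive step length and the
        extrapolation is kept only when the restricted likelihood does not
        drop, so the recorded likelihood history stays nondecreasing either
        way (guarded over-relaxation; plain EM is notoriously slow for the
        additive-genetic component).
        """
        vary = float(np.var(self.y)) or 1.0
        floor = 1e-8 * vary
        k = len(self.terms) + 1
        variances = {t.name: vary / k for t in self.terms}
        variances["residual"] = vary / k
        if init:
            variances.update(init)
        history = []
        converged = False
        step = 1.0
        for it in range(max_iter):
            raw = self.solve(variances)
            m2_cur = self._minus2_reml(variances, raw)
            history.append(-0.5 * m2_cur)
            new = self._em_update(variances, raw, floor, fix_residual)
            if any(v <= floor * (1 + 1e-9) for v in new.values()):
                warnings.warn("variance component pinned at floor", stacklevel=2)
            # convergence is judged on the plain EM step: near the optimum
            # the EM update barely moves even when extrapolation still does
            rel = max(
                abs(new[key] - variances[key]) / max(variances[key], floor)
                for key in new
            )
            chosen = new
            if accelerate and rel >= tol:
                step = min(max(step * 2.0, 2.0), 16.0)
                while step > 1.0:
                    cand = {
                        key: variances[key] + step * (new[key] - variances[key])
                        for key in new
                    }
                    if min(cand.values()) > floor:
                        raw_c = self.solve(cand, compute_cinv=False)
                        if self._minus2_reml(cand, raw_c) <= m2_cur:
                            chosen = cand
                            break
                    step /= 2.0
            variances = chosen
            if verbose:
                print(f"EM iter {it} (step {step}): {variances}")
            if rel < tol:
                converged = True
                break
        raw = self.solve(variances)
        history.append(-0.5 * self._minus2_reml(variances, raw))
        fit = self._package(variances, raw)
        fit.converged = converged
        fit.history = history
        if not converged:
            warnings.warn("EM-REML hit max_iter without converging", stacklevel=2)
        return fit

    def _em_update(self, variances: dict, raw, floor: float,
                   fix_residual: bool) -> dict:
        """One classical EM-REML update of every variance component."""
        new = {}
        sigma_e2 = variances["residual"]
        for t, slc in self._kept_slices:
            u = raw["sol_keep"][slc]
            Cblock = raw["Sinv"][slc, slc]
            if t.ginv is None:
                quad = float(u @ u)
                tr = float(np.trace(Cblock))
            else:
                quad = float(u @ (t.ginv @ u))
                G = t.ginv.tocoo()
                tr = float(np.sum(G.data * Cblock[G.row, G.col]))
            new[t.name] = max((quad + sigma_e2 * tr) / t.q, floor)
        for t, slc in self._abs_slices:
            u = raw["sol_abs"][slc]
            tr = float(raw["diag_abs"][slc].sum())
            new[t.name] = max((float(u @ u) + sigma_e2 * tr) / t.q, floor)
        if fix_residual:
            new["residual"] = variances["residual"]
        else:
            resid_ss = self._yty - self._sol_rhs_product(raw)
            new["residual"] = max(resid_ss / (len(self.y) - self.p), floor)
        return new

    # -- packaging ---------------------------------------------------------

    def _package(self, variances: dict, raw) -> MMEFit:
        sigma_e2 = variances["residual"]
        beta = pd.Series(raw["sol_keep"][: self.p], index=self.design.names)
        u = {}
        diag_cinv = {}
        for t, slc in self._kept_slices:
            u[t.name] = pd.Series(raw["sol_keep"][slc], index=t.levels)
            diag_cinv[t.name] = np.diag(raw["Sinv"])[slc].copy()
        for t, slc in self._abs_slices:
            u[t.name] = pd.Series(raw["sol_abs"][slc], index=t.levels)
            diag_cinv[t.name] = raw["diag_abs"][slc].copy()
        cov_beta = sigma_e2 * raw["Sinv"][: self.p, : self.p]
        return MMEFit(
            beta=beta,
            u=u,
            variances=dict(variances),
            diag_cinv=diag_cinv,
            cov_beta=cov_beta,
            sigma_e2=sigma_e2,
            n_obs=len(self.y),
            rank_x=self.p,
            minus2_reml=self._minus2_reml(variances, raw),
            design=self.design,
        )
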
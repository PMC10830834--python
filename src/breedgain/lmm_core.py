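"""Linear mixed-model engine.

Builds design matrices from a data frame, estimates variance components by
REML, and solves Henderson's mixed-model equations (MME) for BLUEs/SEs of
fixed effects and BLUPs/PEVs of random effects.

The model is

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k K_k),   e ~ N(0, s2_e W^-1)

where each K_k is either the identity (IID term) or a supplied covariance
structure (e.g. a pedigree relationship matrix), and W is a diagonal matrix
of known observation weights (precisions relative to s2_e).

REML is maximised over log-variances by bounded quasi-Newton; the likelihood
is evaluated through the Cholesky factorisation of the MME coefficient matrix

    C = [X' R^-1 X   X' R^-1 Z ]
        [Z' R^-1 X   Z' R^-1 Z + G^-1]

using  -2 l_R = log|R| + log|G| + log|C| + y' P y  (up to a constant).
Fixed-effect covariances and random-effect prediction error variances (PEV)
are read from the corresponding blocks of C^-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize

logger = logging.getLogger("breedgain")

#: variance floor, as a multiple of var(response)
VARIANCE_FLOOR_FACTOR = 1e-8


class RankDeficiencyError(ValueError):
    """Fixed-effect design is singular even after column pruning."""


@dataclass
class RandomTerm:
    """One random term of the model.

    Parameters
    ----------
    factor : str
        Column name of the grouping factor.
    covariance : ndarray, optional
        Level covariance structure K (e.g. an additive relationship matrix).
        ``None`` means IID levels (K = I).
    levels : sequence, optional
        Level order matching the rows of ``covariance``.  Required when a
        covariance is supplied; levels absent from the data still receive
        predictions through K.
    """

    factor: str
    covariance: Optional[np.ndarray] = None
    levels: Optional[Sequence] = None

    def __post_init__(self) -> None:
        if self.covariance is not None and self.levels is None:
            raise ValueError(f"random term {self.factor!r}: covariance given without levels")


@dataclass
class ModelSpec:
    response: str
    fixed: list = field(default_factory=list)
    random: list = field(default_factory=list)  # list[RandomTerm]
    weights: Optional[str] = None
    #: factor coded with a full set of indicators and no intercept
    #: (cell-means coding); all other factors are treatment coded.
    cell_means: Optional[str] = None

    def __post_init__(self) -> None:
        random_names = {t.factor for t in self.random}
        overlap = random_names.intersection(self.fixed)
        if overlap:
            raise ValueError(f"terms both fixed and random: {sorted(overlap)}")


@dataclass
class DesignMatrices:
    y: np.ndarray
    X: np.ndarray
    fixed_names: list
    Z: list  # list[ndarray], one incidence block per random term
    random_levels: list  # list[list], level order per term
    terms: list  # list[RandomTerm]
    weights: np.ndarray
    rows_kept: np.ndarray  # positional index into the original table
    #: per-factor level → column mapping for contrast construction
    factor_columns: dict = field(default_factory=dict)
    has_intercept: bool = True
    dropped_columns: list = field(default_factory=list)
    log: list = field(default_factory=list)


@dataclass
class VarianceComponents:
    sigma2: dict  # term factor name -> s2, plus "residual"
    converged: bool
    n_iterations: int
    reml_loglik: float
    clamped: list = field(default_factory=list)

    @property
    def residual(self) -> float:
        return self.sigma2["residual"]


@dataclass
class MMEFit:
    beta: np.ndarray
    beta_cov: np.ndarray
    fixed_names: list
    u: dict  # term -> ndarray of predictions
    pev: dict  # term -> ndarray, diagonal PEV per level
    pev_matrix: dict  # term -> full PEV block of C^-1
    random_levels: dict  # term -> level list
    vc: VarianceComponents
    dm: DesignMatrices

    @property
    def beta_se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.beta_cov), 0.0, None))


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _is_numeric(col: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(col) and not isinstance(
        col.dtype, pd.CategoricalDtype
    )


def build_design(table: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Assemble response, fixed and random design matrices.

    Fixed factors are treatment coded against their first observed level
    (drop order: input order of levels); the ``cell_means`` factor, if any,
    gets a full indicator block and suppresses the intercept.  Rows with a
    missing response, missing fixed covariate/factor, or missing weight are
    dropped and logged.  Linearly dependent fixed columns are pruned by
    pivoted QR (drop order: rightmost dependent columns first).
    """
    log: list = []
    needed = [spec.response] + list(spec.fixed)
    if spec.weights:
        needed.append(spec.weights)
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise KeyError(f"columns not in table: {missing_cols}")

    keep = table[spec.response].notna()
    for term in spec.fixed:
        keep &= table[term].notna()
    if spec.weights:
        keep &= table[spec.weights].notna()
    n_drop = int((~keep).sum())
    if n_drop:
        log.append(f"dropped {n_drop} rows with missing response/covariate/weight")
    sub = table.loc[keep]
    rows_kept = np.flatnonzero(keep.to_numpy())
    y = sub[spec.response].to_numpy(dtype=float)
    n = len(sub)

    if spec.weights:
        w = sub[spec.weights].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
    else:
        w = np.ones(n)

    cols: list = []
    names: list = []
    factor_columns: dict = {}
    has_intercept = spec.cell_means is None
    if has_intercept:
        cols.append(np.ones(n))
        names.append("(Intercept)")
    for term in spec.fixed:
        col = sub[term]
        if _is_numeric(col):
            v = col.to_numpy(dtype=float)
            if n and np.ptp(v) == 0:
                log.append(f"covariate {term!r} constant after row drops; removed")
                logger.warning("covariate %r constant; removed from model", term)
                continue
            cols.append(v)
            names.append(term)
        else:
            levels = list(pd.unique(col.astype(str)))
            drop_first = term != spec.cell_means
            used = levels[1:] if drop_first else levels
            factor_columns[term] = {}
            codes = col.astype(str).to_numpy()
            for lev in used:
                cols.append((codes == lev).astype(float))
                names.append(f"{term}[{lev}]")
                factor_columns[term][lev] = len(names) - 1
            if drop_first and levels:
                factor_columns[term].setdefault(levels[0], None)  # reference
    X = np.column_stack(cols) if cols else np.empty((n, 0))

    dropped: list = []
    if X.shape[1]:
        # prune linearly dependent columns, keeping earlier columns
        _, R, piv = sla.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
        rank = int(np.sum(diag > tol))
        if rank < X.shape[1]:
            drop_idx = sorted(piv[rank:], reverse=True)
            for j in drop_idx:
                dropped.append(names[j])
            keep_idx = sorted(piv[:rank])
            X = X[:, keep_idx]
            remap = {old: new for new, old in enumerate(keep_idx)}
            names = [names[j] for j in keep_idx]
            for term, mapping in factor_columns.items():
                factor_columns[term] = {
                    lev: (remap.get(j) if j is not None else None)
                    for lev, j in mapping.items()
                }
            log.append(f"dropped rank-deficient fixed columns: {dropped}")
            logger.info("dropped rank-deficient fixed columns: %s", dropped)

    Z_list: list = []
    level_list: list = []
    for term in spec.random:
        col = sub[term.factor]
        codes = col.astype(str).where(col.notna(), other=None)
        if term.levels is not None:
            levels = [str(l) for l in term.levels]
        else:
            levels = [l for l in pd.unique(codes.dropna())]
        index = {lev: j for j, lev in enumerate(levels)}
        Z = np.zeros((n, len(levels)))
        arr = codes.to_numpy()
        for i in range(n):
            lev = arr[i]
            if lev is not None and lev in index:
                Z[i, index[lev]] = 1.0
            elif lev is not None:
                raise ValueError(
                    f"level {lev!r} of {term.factor!r} missing from supplied covariance levels"
                )
        Z_list.append(Z)
        level_list.append(levels)

    return DesignMatrices(
        y=y, X=X, fixed_names=names, Z=Z_list, random_levels=level_list,
        terms=list(spec.random), weights=w, rows_kept=rows_kept,
        factor_columns=factor_columns, has_intercept=has_intercept,
        dropped_columns=dropped, log=log,
    )


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _term_structures(dm: DesignMatrices):
    """Cholesky-based inverse and log-determinant of each K_k (once)."""
    Kinvs, logdets = [], []
    for term, levels in zip(dm.terms, dm.random_levels):
        q = len(levels)
        if term.covariance is None:
            Kinvs.append(None)
            logdets.append(0.0)
        else:
            K = np.asarray(term.covariance, dtype=float)
            if K.shape != (q, q):
                raise ValueError(
                    f"covariance for {term.factor!r} has shape {K.shape}, expected {(q, q)}"
                )
            try:
                cf = sla.cho_factor(K, lower=True)
            except sla.LinAlgError:
                jitter = 1e-8 * np.trace(K) / q
                logger.info("jittering covariance of %r by %g", term.factor, jitter)
                cf = sla.cho_factor(K + jitter * np.eye(q), lower=True)
            Kinvs.append(sla.cho_solve(cf, np.eye(q)))
            logdets.append(2.0 * np.sum(np.log(np.diag(cf[0]))))
    return Kinvs, logdets


def _mme_pieces(dm: DesignMatrices):
    M = np.hstack([dm.X] + dm.Z) if dm.Z else dm.X
    Wy = dm.weights * dm.y
    A0 = M.T @ (dm.weights[:, None] * M)
    r0 = M.T @ Wy
    yy = float(dm.y @ Wy)
    return M, A0, r0, yy


def _assemble_C(A0, dm, s2, Kinvs):
    s_e = s2[-1]
    C = A0 / s_e
    p = dm.X.shape[1]
    off = p
    for k, levels in enumerate(dm.random_levels):
        q = len(levels)
        sl = slice(off, off + q)
        if Kinvs[k] is None:
            C[sl, sl] += np.eye(q) / s2[k]
        else:
            C[sl, sl] += Kinvs[k] / s2[k]
        off += q
    return C


def _neg2_reml(log_s2, A0, r0, yy, dm, Kinvs, K_logdets):
    s2 = np.exp(np.clip(log_s2, -100.0, 100.0))
    s_e = s2[-1]
    n, p = dm.X.shape
    C = _assemble_C(A0, dm, s2, Kinvs)
    try:
        cf = sla.cho_factor(C, lower=True)
    except sla.LinAlgError:
        return 1e30
    logdet_C = 2.0 * np.sum(np.log(np.diag(cf[0])))
    rhs = r0 / s_e
    b = sla.cho_solve(cf, rhs)
    yPy = yy / s_e - float(b @ rhs)
    logdet_R = n * np.log(s_e) - float(np.sum(np.log(dm.weights)))
    logdet_G = 0.0
    for k, levels in enumerate(dm.random_levels):
        logdet_G += len(levels) * np.log(s2[k]) + K_logdets[k]
    return logdet_R + logdet_G + logdet_C + yPy


def reml_fit(dm: DesignMatrices, max_iter: int = 200) -> VarianceComponents:
    """Estimate variance components by REML.

    Optimisation is bounded L-BFGS-B on log-variances with a deterministic
    method-of-moments start (the OLS residual variance, split evenly between
    the residual and the random terms).  Components that finish at the lower
    bound are clamped to the floor and flagged.
    """
    n, p = dm.X.shape
    n_terms = len(dm.terms)
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    var_y = float(np.var(dm.y)) if n > 1 else 1.0
    if var_y <= 0:
        var_y = 1.0
    floor = VARIANCE_FLOOR_FACTOR * var_y
    Kinvs, K_logdets = _term_structures(dm)
    _, A0, r0, yy = _mme_pieces(dm)

    # method-of-moments start: OLS residual variance split across components
    if p:
        beta0, *_ = np.linalg.lstsq(dm.X * np.sqrt(dm.weights)[:, None],
                                    dm.y * np.sqrt(dm.weights), rcond=None)
        rss = float(np.sum(dm.weights * (dm.y - dm.X @ beta0) ** 2))
        s2_hat = rss / max(n - p, 1)
    else:
        s2_hat = var_y
    s2_hat = max(s2_hat, floor * 10)
    if n_terms:
        start = [0.5 * s2_hat / n_terms] * n_terms + [0.5 * s2_hat]
    else:
        start = [s2_hat]
    x0 = np.log(np.maximum(start, floor))
    bounds = [(np.log(floor), np.log(max(1e8 * var_y, floor * 10)))] * (n_terms + 1)

    res = minimize(
        _neg2_reml, x0, args=(A0, r0, yy, dm, Kinvs, K_logdets),
        method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": max_iter},
    )
    n_iter = int(res.nit)
    best_x, best_fun = res.x, res.fun
    if A0.shape[0] <= 400:
        # derivative-free polish: the quasi-Newton stop with numeric
        # gradients leaves ~1e-6 relative slack along flat log-variance
        # directions; cheap to remove on small coefficient matrices
        polish = minimize(
            _neg2_reml, best_x, args=(A0, r0, yy, dm, Kinvs, K_logdets),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 150},
        )
        if polish.fun <= best_fun:
            best_x, best_fun = polish.x, polish.fun
        n_iter += int(polish.nit)
    best_x = np.clip(best_x, [b[0] for b in bounds], [b[1] for b in bounds])
    s2 = np.exp(best_x)
    clamped = []
    names = [t.factor for t in dm.terms] + ["residual"]
    for j, name in enumerate(names):
        if s2[j] <= floor * 1.0001:
            s2[j] = floor
            clamped.append(name)
    if clamped:
        logger.info("variance components clamped at floor: %s", clamped)
    return VarianceComponents(
        sigma2=dict(zip(names, s2.tolist())),
        converged=bool(res.success),
        n_iterations=n_iter,
        reml_loglik=-0.5 * float(best_fun),
        clamped=clamped,
    )


# ---------------------------------------------------------------------------
# MME solve
# ---------------------------------------------------------------------------

def solve_mme(dm: DesignMatrices, vc: VarianceComponents) -> MMEFit:
    """Solve Henderson's MME at the given variance components.

    Fixed-effect covariances and per-level PEVs come from the inverse
    coefficient matrix (full blocks, no approximation).
    """
    n, p = dm.X.shape
    names = [t.factor for t in dm.terms]
    s2 = np.array([vc.sigma2[name] for name in names] + [vc.sigma2["residual"]])
    Kinvs, _ = _term_structures(dm)
    _, A0, r0, yy = _mme_pieces(dm)
    C = _assemble_C(A0, dm, s2, Kinvs)
    try:
        cf = sla.cho_factor(C, lower=True)
    except sla.LinAlgError as exc:
        raise RankDeficiencyError(
            f"MME coefficient matrix singular; fixed columns: {dm.fixed_names}"
        ) from exc
    rhs = r0 / s2[-1]
    b = sla.cho_solve(cf, rhs)
    Cinv = sla.cho_solve(cf, np.eye(C.shape[0]))

    beta = b[:p]
    beta_cov = Cinv[:p, :p]
    u, pev, pev_mat, rl = {}, {}, {}, {}
    off = p
    for k, term in enumerate(dm.terms):
        q = len(dm.random_levels[k])
        sl = slice(off, off + q)
        u[term.factor] = b[sl]
        block = Cinv[sl, sl]
        pev[term.factor] = np.clip(np.diag(block).copy(), 0.0, None)
        pev_mat[term.factor] = block
        rl[term.factor] = dm.random_levels[k]
        off += q
    return MMEFit(
        beta=beta, beta_cov=beta_cov, fixed_names=dm.fixed_names,
        u=u, pev=pev, pev_matrix=pev_mat, random_levels=rl, vc=vc, dm=dm,
    )


def fit_model(table: pd.DataFrame, spec: ModelSpec) -> MMEFit:
    """Convenience wrapper: build design, REML, solve MME."""
    dm = build_design(table, spec)
    vc = reml_fit(dm)
    return solve_mme(dm, vc)


def adjusted_means(fit: MMEFit, factor: str) -> pd.DataFrame:
    """Adjusted means (BLUEs) and SEs for each level of a fixed factor.

    The mean for level l is the fitted value at that level with every other
    fixed factor averaged over its levels and covariates held at zero (the
    caller centres covariates beforehand); random effects are at zero.
    """
    dm = fit.dm
    if factor not in dm.factor_columns:
        raise KeyError(f"{factor!r} is not a fixed factor of the model")
    p = len(fit.fixed_names)
    base = np.zeros(p)
    if dm.has_intercept:
        base[fit.fixed_names.index("(Intercept)")] = 1.0
    for other, mapping in dm.factor_columns.items():
        if other == factor:
            continue
        k = len(mapping)
        for lev, j in mapping.items():
            if j is not None:
                base[j] += 1.0 / k
    out = []
    for lev, j in dm.factor_columns[factor].items():
        c = base.copy()
        if j is not None:
            c[j] += 1.0
        est = float(c @ fit.beta)
        se = float(np.sqrt(max(c @ fit.beta_cov @ c, 0.0)))
        out.append((lev, est, se))
    return pd.DataFrame(out, columns=["level", "estimate", "se"])
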
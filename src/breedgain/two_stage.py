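"""Two-stage weighted mixed-model analysis of multi-environment trials.

Stage 1 fits, per year, a model with genotype fixed (cell means), days to
flowering as a fixed covariate, and season plus the design blocking factors
(replicate/block or row/column, made unique per trial) as IID random
effects; it emits one BLUE, SE and weight = 1/SE^2 per genotype per year.

Per year x season slice, a modified model (genotype random, no season term)
yields the generalized Cullis heritability

    H2 = 1 - Vbar_BLUP / (2 * s2_g)

with Vbar_BLUP the mean variance of a difference between two genotype
BLUPs, computed from the full PEV block of the mixed-model equations.

Stage 2 regresses the stage-1 BLUEs on year (fixed) with genotype random
under covariance s2_g * A (pedigree mode) or s2_g * I (no-pedigree mode,
plain BLUPs), with the stage-1 weights entering as known residual
precisions.  Reliability is r = 1 - PEV/s2_g, clamped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .lmm_core import (
    MMEFit, ModelSpec, RandomTerm, VarianceComponents, adjusted_means,
    build_design, reml_fit, solve_mme,
)
from .pedigree_kinship import AMatrix

logger = logging.getLogger("breedgain")

DESIGN_FACTORS = ["rep", "block", "row", "col"]


@dataclass
class Stage1Result:
    blues: pd.DataFrame          # year, genotype, blue, se, weight
    h2: pd.DataFrame             # year, season, h2, sigma2_g, clamped
    diagnostics: dict = field(default_factory=dict)
    skipped_years: list = field(default_factory=list)


@dataclass
class H2Result:
    h2: float
    sigma2_g: float
    sigma2_e: float
    v_blup: float
    clamped: bool


@dataclass
class Stage2Result:
    table: pd.DataFrame          # genotype, breeding_value, pev, reliability, phenotyped
    sigma2_g: float
    sigma2_e: float
    vc: VarianceComponents
    year_effects: pd.DataFrame
    n_reliability_clamps: int
    fit: Optional[MMEFit] = None


def _prepare_year_slice(sub: pd.DataFrame, use_dtf: bool) -> pd.DataFrame:
    sub = sub.copy()
    sub["trial_id"] = (sub["season"].astype(str) + "_"
                       + sub["location"].astype(str))
    for fac in DESIGN_FACTORS:
        if fac in sub.columns:
            vals = sub[fac]
            sub[f"{fac}_t"] = np.where(
                vals.notna(), sub["trial_id"] + ":" + vals.astype(str), None)
    if use_dtf and "dtf" in sub.columns:
        mean_dtf = sub.loc[sub["yield_kg_ha"].notna(), "dtf"].mean()
        sub["dtf_c"] = sub["dtf"] - mean_dtf
    return sub


def _random_terms(sub: pd.DataFrame, include_season: bool,
                  extra_exclude=()) -> list:
    terms = []
    if include_season and sub["season"].nunique() > 1:
        terms.append(RandomTerm("season"))
    if sub["location"].nunique() > 1:
        terms.append(RandomTerm("location"))
    for fac in DESIGN_FACTORS:
        col = f"{fac}_t"
        if fac in extra_exclude or col not in sub.columns:
            continue
        if sub[col].dropna().nunique() > 1:
            terms.append(RandomTerm(col))
    return terms


def stage1_by_year(table: pd.DataFrame, use_dtf_covariate: bool = True,
                   season_role: str = "random") -> Stage1Result:
    """Per-year stage-1 fits emitting genotype BLUEs, SEs and weights.

    ``season_role`` selects whether season enters as a random ("random",
    default) or fixed ("fixed") effect.  Years whose model cannot be fit
    (confounded or empty) are skipped with a logged reason.
    """
    if season_role not in ("random", "fixed"):
        raise ValueError("season_role must be 'random' or 'fixed'")
    blues_rows, h2_rows = [], []
    diagnostics, skipped = {}, []
    for year, raw in table.groupby("year", sort=True):
        sub = _prepare_year_slice(raw, use_dtf_covariate)
        n_obs = int(sub["yield_kg_ha"].notna().sum())
        if n_obs < 3 or sub.loc[sub["yield_kg_ha"].notna(), "genotype"].nunique() < 2:
            skipped.append((year, "too few observations"))
            continue
        fixed = ["genotype"]
        if use_dtf_covariate and "dtf_c" in sub.columns:
            fixed.append("dtf_c")
        if season_role == "fixed" and sub["season"].nunique() > 1:
            fixed.append("season")
        spec = ModelSpec(
            response="yield_kg_ha", fixed=fixed,
            random=_random_terms(sub, include_season=season_role == "random"),
            cell_means="genotype",
        )
        try:
            dm = build_design(sub, spec)
            vc = reml_fit(dm)
            fit = solve_mme(dm, vc)
            means = adjusted_means(fit, "genotype")
        except Exception as exc:  # confounded/degenerate year
            skipped.append((year, str(exc)))
            logger.warning("stage 1 year %s skipped: %s", year, exc)
            continue
        for _, r in means.iterrows():
            if r["se"] <= 0 or not np.isfinite(r["se"]):
                continue
            blues_rows.append({
                "year": year, "genotype": r["level"], "blue": r["estimate"],
                "se": r["se"], "weight": 1.0 / r["se"] ** 2,
            })
        diag = {
            "n_obs": n_obs, "converged": vc.converged,
            "sigma2": vc.sigma2, "clamped": vc.clamped,
            "design_log": dm.log,
        }
        if "dtf_c" in fit.fixed_names:
            j = fit.fixed_names.index("dtf_c")
            diag["dtf_coefficient"] = float(fit.beta[j])
            diag["dtf_coefficient_se"] = float(fit.beta_se[j])
        diagnostics[year] = diag
        for season, chunk in sub.groupby("season"):
            if chunk.loc[chunk["yield_kg_ha"].notna(), "genotype"].nunique() < 2:
                continue
            try:
                res = cullis_h2(chunk, use_dtf_covariate=use_dtf_covariate,
                                _prepared=True)
            except Exception as exc:
                logger.warning("H2 for %s/%s skipped: %s", year, season, exc)
                continue
            h2_rows.append({"year": year, "season": season, "h2": res.h2,
                            "sigma2_g": res.sigma2_g, "clamped": res.clamped})
    blues = pd.DataFrame(blues_rows,
                         columns=["year", "genotype", "blue", "se", "weight"])
    h2 = pd.DataFrame(h2_rows,
                      columns=["year", "season", "h2", "sigma2_g", "clamped"])
    return Stage1Result(blues=blues, h2=h2, diagnostics=diagnostics,
                        skipped_years=skipped)


def cullis_h2(table_one_year_one_season: pd.DataFrame,
              use_dtf_covariate: bool = True,
              vc: Optional[VarianceComponents] = None,
              _prepared: bool = False) -> H2Result:
    """Generalized (Cullis) heritability for one year x season slice.

    Genotype is random (IID), design factors random, DTF a fixed covariate,
    no season term.  ``vc`` may supply known variance components, in which
    case REML is skipped and the PEV algebra is evaluated at those values.
    Returns H2 = 1 - Vbar/(2 s2_g) clamped to [0, 1]; when s2_g sits at the
    boundary floor, H2 = 0 with the clamped flag set.
    """
    sub = table_one_year_one_season
    if not _prepared:
        sub = _prepare_year_slice(sub, use_dtf_covariate)
    if sub.loc[sub["yield_kg_ha"].notna(), "genotype"].nunique() < 2:
        raise ValueError("need >= 2 genotypes with records")
    fixed = []
    if use_dtf_covariate and "dtf_c" in sub.columns:
        fixed.append("dtf_c")
    random = [RandomTerm("genotype")] + _random_terms(sub, include_season=False)
    spec = ModelSpec(response="yield_kg_ha", fixed=fixed, random=random)
    dm = build_design(sub, spec)
    if vc is None:
        vc = reml_fit(dm)
    fit = solve_mme(dm, vc)
    s2g = vc.sigma2["genotype"]
    clamped = "genotype" in vc.clamped
    if clamped or s2g <= 0:
        return H2Result(0.0, s2g, vc.residual, float("nan"), True)
    P = fit.pev_matrix["genotype"]
    q = P.shape[0]
    v_blup = 2.0 * (q * np.trace(P) - P.sum()) / (q * (q - 1))
    h2 = float(np.clip(1.0 - v_blup / (2.0 * s2g), 0.0, 1.0))
    return H2Result(h2, s2g, vc.residual, float(v_blup), False)


def stage2_blup(s1: Stage1Result, a: Optional[AMatrix] = None,
                vc: Optional[VarianceComponents] = None) -> Stage2Result:
    """Stage-2 weighted fit of the stage-1 BLUEs.

    Year is fixed; genotype is random with covariance s2_g*A when a
    relationship matrix is supplied (breeding values) or s2_g*I otherwise
    (plain BLUPs).  Weights = stage-1 1/SE^2 enter the diagonal residual
    covariance.  Breeding values are reported on the phenotypic scale: the
    mean fitted year level plus the genotype prediction.  Genotypes present
    only in the pedigree still receive predictions through A.  ``vc`` may
    supply known variance components, skipping REML.
    """
    blues = s1.blues
    if blues.empty:
        raise ValueError("stage-1 result is empty")
    df = blues.copy()
    df["year_f"] = df["year"].astype(str)
    genos = sorted(df["genotype"].unique())
    if a is not None:
        missing = [g for g in genos if g not in a.index]
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped genotypes missing from A: {missing[:10]}")
        term = RandomTerm("genotype", covariance=a.values, levels=a.ids)
    else:
        term = RandomTerm("genotype")
    spec = ModelSpec(response="blue", fixed=["year_f"], random=[term],
                     weights="weight")
    dm = build_design(df, spec)
    if vc is None:
        vc = reml_fit(dm)
    fit = solve_mme(dm, vc)
    s2g = vc.sigma2["genotype"]
    s2e = vc.residual

    # mean fitted year level (intercept + average year contrast)
    year_map = fit.dm.factor_columns.get("year_f", {})
    intercept = fit.beta[fit.fixed_names.index("(Intercept)")] \
        if "(Intercept)" in fit.fixed_names else 0.0
    effects = []
    for lev, j in year_map.items():
        effects.append((lev, intercept + (fit.beta[j] if j is not None else 0.0)))
    year_effects = pd.DataFrame(effects, columns=["year", "effect"])
    base = float(year_effects["effect"].mean()) if len(year_effects) else float(intercept)

    levels = fit.random_levels["genotype"]
    u = fit.u["genotype"]
    pev = fit.pev["genotype"]
    if a is not None:
        prior = s2g * np.diag(a.values)
    else:
        prior = np.full(len(levels), s2g)
    rel_raw = 1.0 - pev / s2g
    n_clamps = int(np.sum((rel_raw < 0) | (rel_raw > 1)))
    if n_clamps:
        logger.info("reliability clamped for %d genotypes", n_clamps)
    reliability = np.clip(rel_raw, 0.0, 1.0)
    phenotyped = np.isin(levels, genos)
    out = pd.DataFrame({
        "genotype": levels,
        "breeding_value": base + u,
        "pev": pev,
        "reliability": reliability,
        "phenotyped": phenotyped,
        "prior_variance": prior,
    })
    return Stage2Result(table=out, sigma2_g=float(s2g), sigma2_e=float(s2e),
                        vc=vc, year_effects=year_effects,
                        n_reliability_clamps=n_clamps, fit=fit)
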
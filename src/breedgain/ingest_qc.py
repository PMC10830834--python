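"""Phenotype ingestion and quality control.

Trial-level filters drop trials (year x season x location) with more than a
missing-yield threshold, entirely absent design-mandated factor columns
(missing replication / design error), or implausible yields.  Observation-
level screening flags outliers per trial by studentized residuals from a
stage-1-style working mixed model (genotype and the available design
factors random), with Holm's step-down multiplicity correction at
family-wise level alpha within each trial; flagged yields are set to
missing so the design structure is kept.

The working model is mixed, not fixed-effects: with genotype cell means an
unreplicated entry (augmented designs) has leverage one and its residual is
identically zero, and a row-column model is so heavily parameterised that
an 8-sigma shift loses half its magnitude to leverage.  Shrinkage of the
random genotype effect keeps every plot testable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("breedgain")

TRIAL_KEYS = ["year", "season", "location"]

#: factor columns that must be present (not entirely missing) per design
DESIGN_REQUIRED = {
    "rcbd": ["rep", "block"],
    "augmented_rcbd": ["rep", "block"],
    "alpha_lattice": ["rep", "block"],
    "row_column": ["row", "col"],
}

MANDATORY_COLUMNS = ["genotype", "year", "season", "location", "yield_kg_ha"]


class SchemaError(ValueError):
    pass


@dataclass
class QCReport:
    trials_in: int = 0
    trials_dropped: dict = field(default_factory=dict)  # reason -> [trial keys]
    outliers_flagged: list = field(default_factory=list)  # (row id, t, p_adj)
    records_retained: int = 0
    log: list = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return sum(len(v) for v in self.trials_dropped.values())

    def to_json(self, path=None):
        d = {
            "trials_in": self.trials_in,
            "trials_dropped": {k: [list(map(str, t)) for t in v]
                               for k, v in self.trials_dropped.items()},
            "outliers_flagged": [
                {"record": int(i), "studentized_residual": float(t),
                 "p_adjusted": float(p)}
                for i, t, p in self.outliers_flagged
            ],
            "records_retained": int(self.records_retained),
            "log": self.log,
        }
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=1))
        return d


def read_phenotypes(path) -> tuple[pd.DataFrame, list]:
    """Read a phenotype CSV into a typed table.

    Unparseable yield cells become missing values (with a log entry), never
    errors; missing mandatory columns raise :class:`SchemaError`.
    Returns (table, parse log).
    """
    table = pd.read_csv(path, dtype=str)
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"phenotype file missing mandatory columns: {missing}")
    log = []
    raw = table["yield_kg_ha"]
    table["yield_kg_ha"] = pd.to_numeric(raw, errors="coerce")
    bad = raw.notna() & table["yield_kg_ha"].isna()
    n_bad = int(bad.sum())
    if n_bad:
        log.append(f"{n_bad} unparseable yield cells set to missing")
    table["year"] = pd.to_numeric(table["year"], errors="coerce").astype("Int64")
    if "dtf" in table.columns:
        table["dtf"] = pd.to_numeric(table["dtf"], errors="coerce")
    for col in ("rep", "block", "row", "col"):
        if col not in table.columns:
            table[col] = pd.NA
    return table, log


def filter_trials(table: pd.DataFrame, max_missing: float = 0.20,
                  aberrant_max: float = 20_000.0) -> tuple[pd.DataFrame, QCReport]:
    """Drop whole trials failing the pre-processing filters.

    A trial is one (year, season, location) combination.  Drop reasons:

    * ``excess_missing`` — missing-yield proportion strictly above
      ``max_missing`` (a trial at exactly the threshold is retained);
    * ``missing_replication`` / ``design_error`` — a factor column mandated
      by the trial's design is entirely absent;
    * ``aberrant_values`` — any yield outside [0, ``aberrant_max``] kg/ha.
    """
    report = QCReport()
    groups = table.groupby(TRIAL_KEYS, dropna=False, sort=False)
    report.trials_in = groups.ngroups
    keep_parts = []
    for key, grp in groups:
        reason = None
        miss = grp["yield_kg_ha"].isna().mean() if len(grp) else 0.0
        y = grp["yield_kg_ha"].dropna()
        designs = grp["design"].dropna().unique() if "design" in grp.columns else []
        required = set()
        for d in designs:
            required.update(DESIGN_REQUIRED.get(str(d), []))
        absent = [c for c in required if grp[c].isna().all()]
        if miss > max_missing:
            reason = "excess_missing"
        elif absent:
            reason = ("missing_replication"
                      if set(absent) & {"rep", "block"} else "design_error")
        elif len(y) and ((y < 0).any() or (y > aberrant_max).any()):
            reason = "aberrant_values"
        if reason:
            report.trials_dropped.setdefault(reason, []).append(key)
            logger.info("trial %s dropped: %s", key, reason)
        else:
            keep_parts.append(grp)
    out = (pd.concat(keep_parts) if keep_parts
           else table.iloc[0:0]).copy()
    report.records_retained = len(out)
    return out, report


def _studentized_residuals(grp: pd.DataFrame):
    """Studentized residuals from the per-trial working mixed model.

    Fits intercept fixed + genotype and available design factors random by
    REML, then standardises the conditional residuals by their exact
    covariance R P R (P the projection kernel of the marginal model); the
    internal statistics are mapped to externally studentized (deletion)
    form with the residual df of the fixed part.  Returns (t, df, kept
    positions into grp) or (None, df, None) when df < 2.
    """
    from .lmm_core import ModelSpec, RandomTerm, build_design, reml_fit

    random = [RandomTerm("genotype")]
    for fac in ("rep", "block", "row", "col"):
        if (fac in grp.columns and grp[fac].notna().any()
                and grp[fac].dropna().nunique() > 1):
            random.append(RandomTerm(fac))
    spec = ModelSpec(response="yield_kg_ha", fixed=[], random=random)
    dm = build_design(grp, spec)
    n, p = dm.X.shape
    df = n - p
    if df < 2:
        return None, df, None
    vc = reml_fit(dm)
    V = vc.residual * np.eye(n)
    for k, term in enumerate(dm.terms):
        V += vc.sigma2[term.factor] * dm.Z[k] @ dm.Z[k].T
    Vi = np.linalg.inv(V)
    X = dm.X
    P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
    Py = P @ dm.y
    d = np.clip(np.diag(P), 1e-300, None)
    r = Py / np.sqrt(d)
    r2 = np.clip(r**2, 0.0, df - 1e-9)
    t = r * np.sqrt((df - 1) / (df - r2))
    return t, df, dm.rows_kept


def _holm(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Holm step-down: boolean rejection mask and implicitly adjusted p."""
    m = len(pvals)
    order = np.argsort(pvals)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def detect_outliers_bh(table: pd.DataFrame,
                       alpha: float = 0.05) -> tuple[pd.DataFrame, QCReport]:
    """Flag outlying yields per trial by the Bonferroni-Holm studentized-
    residual test and set them to missing.

    Per trial, a stage-1-style working mixed model (genotype + available
    design factors) gives studentized (deletion-form) residuals; two-sided
    p-values use the t distribution with the deletion df; Holm's step-down
    controls the family-wise error at ``alpha`` within the trial.  Trials
    with < 2 residual df are skipped with a warning.  The flag decision
    depends only on the set of records, not their order.
    """
    out = table.copy()
    report = QCReport()
    report.trials_in = out.groupby(TRIAL_KEYS, dropna=False).ngroups
    if alpha < 0 or alpha > 1:
        raise ValueError("alpha must be in [0, 1]")
    for key, grp in out.groupby(TRIAL_KEYS, dropna=False, sort=False):
        obs = grp[grp["yield_kg_ha"].notna()]
        if len(obs) < 3 or alpha == 0:
            continue
        # canonical row order so flagging is order-invariant
        obs = obs.sort_index()
        try:
            t, df, kept = _studentized_residuals(obs)
        except Exception as exc:
            report.log.append(f"trial {key}: outlier test failed ({exc})")
            logger.warning("trial %s: outlier test failed: %s", key, exc)
            continue
        if t is None:
            report.log.append(f"trial {key}: no residual df, outlier test skipped")
            logger.warning("trial %s: zero residual df, outlier test skipped", key)
            continue
        p = 2.0 * stats.t.sf(np.abs(t), df - 1)
        reject = _holm(p, alpha)
        adj = holm_adjust(p)
        idx = obs.index.to_numpy()[kept]
        for i, rej, tt, pa in zip(idx, reject, t, adj):
            if rej:
                out.loc[i, "yield_kg_ha"] = np.nan
                report.outliers_flagged.append((int(i), float(tt), float(pa)))
    report.records_retained = int(out["yield_kg_ha"].notna().sum())
    if report.outliers_flagged:
        logger.info("flagged %d outlying records", len(report.outliers_flagged))
    return out, report


def run_qc(table: pd.DataFrame, max_missing: float = 0.20,
           aberrant_max: float = 20_000.0,
           alpha: float = 0.05) -> tuple[pd.DataFrame, QCReport]:
    """Trial filters followed by per-trial outlier screening; merged report."""
    filtered, rep1 = filter_trials(table, max_missing=max_missing,
                                   aberrant_max=aberrant_max)
    cleaned, rep2 = detect_outliers_bh(filtered, alpha=alpha)
    rep = QCReport(
        trials_in=rep1.trials_in,
        trials_dropped=rep1.trials_dropped,
        outliers_flagged=rep2.outliers_flagged,
        records_retained=rep2.records_retained,
        log=rep1.log + rep2.log,
    )
    return cleaned, rep
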
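"""Pedigree parsing, additive relationship matrix, and diversity PCA.

The additive (numerator) relationship matrix A is built by the tabular
method: processing individuals parents-first,

    a_ii = 1 + 0.5 * a_sd                (s, d the parents of i)
    a_ij = 0.5 * (a_js + a_jd),  j < i

with an unknown parent contributing 0 (treated as an unrelated, non-inbred
founder).  Entries are dyadic rationals; the diagonal is 1 + F_i with F_i
the inbreeding coefficient.

A gene-dropping Monte-Carlo estimator of the same matrix is provided as an
independent verification route: founder alleles are labelled uniquely and
transmitted down the pedigree by fair coin flips; the relationship is twice
the observed probability of identity by descent between random alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter

import numpy as np
import pandas as pd

logger = logging.getLogger("breedgain")

UNKNOWN_PARENT_CODES = {"0", "", "na", "nan", "none", "unknown"}

PEDIGREE_COLUMNS = ["genotype", "parent_f", "parent_m"]


class PedigreeError(ValueError):
    pass


@dataclass
class AMatrix:
    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.ids)}

    def subset(self, ids) -> "AMatrix":
        idx = [self.index[g] for g in ids]
        return AMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _normalize_parent(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s.lower() in UNKNOWN_PARENT_CODES:
        return None
    return s


def sort_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Topologically sort entries parents-first, preserving input order
    among unconstrained entries.  Raises PedigreeError on a cycle, naming
    one member."""
    ids = ped["genotype"].astype(str).tolist()
    dup = pd.Series(ids).duplicated()
    if dup.any():
        raise PedigreeError(f"duplicate genotype ids: {sorted(set(pd.Series(ids)[dup]))}")
    known = set(ids)
    order_rank = {g: i for i, g in enumerate(ids)}
    ts = TopologicalSorter()
    for _, row in ped.iterrows():
        g = str(row["genotype"])
        preds = []
        for pcol in ("parent_f", "parent_m"):
            p = _normalize_parent(row[pcol])
            if p is not None and p in known:
                preds.append(p)
            elif p is not None:
                # parent referenced but absent: treated as unknown founder
                logger.debug("parent %r of %r not in pedigree; treated unknown", p, g)
        ts.add(g, *preds)
    try:
        ts.prepare()
    except CycleError as exc:
        member = exc.args[1][0] if len(exc.args) > 1 and exc.args[1] else "?"
        raise PedigreeError(f"pedigree contains a cycle involving {member!r}") from exc
    ordered = []
    while ts.is_active():
        ready = sorted(ts.get_ready(), key=lambda g: order_rank[g])
        ordered.extend(ready)
        ts.done(*ready)
    out = ped.copy()
    out["genotype"] = out["genotype"].astype(str)
    out = out.set_index("genotype").loc[ordered].reset_index()
    return out


def read_pedigree(path) -> pd.DataFrame:
    """Read a pedigree CSV (genotype, parent_f, parent_m + metadata columns);
    unknown parents coded "0" or empty.  Returns a topologically sorted
    table with unknown parents as None."""
    ped = pd.read_csv(path, dtype=str)
    missing = [c for c in PEDIGREE_COLUMNS if c not in ped.columns]
    if missing:
        raise PedigreeError(f"pedigree file missing columns: {missing}")
    for pcol in ("parent_f", "parent_m"):
        ped[pcol] = ped[pcol].map(_normalize_parent)
    for col in ("year_of_origin", "year_of_release"):
        if col in ped.columns:
            ped[col] = pd.to_numeric(ped[col], errors="coerce")
    if "is_primary" in ped.columns:
        ped["is_primary"] = ped["is_primary"].astype(str).str.lower().isin(
            {"true", "1", "yes"}
        )
    return sort_pedigree(ped)


def build_a_matrix(pedigree: pd.DataFrame) -> AMatrix:
    """Additive relationship matrix by the tabular method.

    The input must be acyclic; it is re-sorted parents-first internally, and
    the result is returned in the (sorted) pedigree order.
    """
    ped = sort_pedigree(pedigree)
    ids = ped["genotype"].tolist()
    index = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    pf = [_normalize_parent(v) for v in ped["parent_f"]]
    pm = [_normalize_parent(v) for v in ped["parent_m"]]
    for i in range(n):
        s = index.get(pf[i]) if pf[i] is not None else None
        d = index.get(pm[i]) if pm[i] is not None else None
        if i:
            row = np.zeros(i)
            if s is not None:
                row += 0.5 * A[s, :i]
            if d is not None:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        a_sd = A[s, d] if (s is not None and d is not None) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
    return AMatrix(ids, A)


def gene_drop_relationship(
    pedigree: pd.DataFrame, n_drops: int = 100_000, rng=None
) -> tuple[AMatrix, np.ndarray]:
    """Monte-Carlo estimate of the relationship matrix by gene dropping.

    Returns (estimate, standard errors).  Each founder receives two unique
    allele labels; every descendant inherits one allele from each parent
    uniformly at random, independently across ``n_drops`` replicates.  The
    estimated relationship a_ij is twice the mean IBD probability between
    random alleles of i and j; its Monte-Carlo SE is 2 * sd/sqrt(n_drops).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ped = sort_pedigree(pedigree)
    ids = ped["genotype"].tolist()
    index = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    pf = [_normalize_parent(v) for v in ped["parent_f"]]
    pm = [_normalize_parent(v) for v in ped["parent_m"]]
    # allele labels: shape (n, 2, n_drops)
    alleles = np.empty((n, 2, n_drops), dtype=np.int32)
    next_founder_allele = 0
    for i in range(n):
        for slot, parent in enumerate((pf[i], pm[i])):
            j = index.get(parent) if parent is not None else None
            if j is None:
                alleles[i, slot, :] = next_founder_allele
                next_founder_allele += 1
            else:
                pick = rng.integers(0, 2, size=n_drops)
                alleles[i, slot, :] = alleles[j, pick, np.arange(n_drops)]
    est = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                stat = (alleles[i, 0] == alleles[i, 1]).astype(np.float64)
                a = 1.0 + stat
            else:
                s = np.zeros(n_drops)
                for p in range(2):
                    for q in range(2):
                        s += alleles[i, p] == alleles[j, q]
                stat = s / 4.0
                a = 2.0 * stat
            est[i, j] = est[j, i] = a.mean()
            se[i, j] = se[j, i] = a.std(ddof=1) / np.sqrt(n_drops)
    return AMatrix(ids, est), se


@dataclass
class BiplotCoordinates:
    ids: list
    scores: np.ndarray  # (n, n_components)
    explained_variance_fraction: np.ndarray  # over ALL components, sums to 1

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{k + 1}": self.scores[:, k] for k in range(self.scores.shape[1])}
        return pd.DataFrame({"genotype": self.ids, **cols})


def pca_on_a(a: AMatrix, n_components: int = 2) -> BiplotCoordinates:
    """PCA of the column-centred relationship matrix, for diversity biplots.

    Rows are treated as observations; scores are U * S of the SVD of the
    centred matrix, and explained-variance fractions cover every component
    (they sum to one).
    """
    X = a.values - a.values.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    frac = s**2 / np.sum(s**2) if np.any(s > 0) else np.full(len(s), 1.0 / len(s))
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        logger.warning("n_components=%d exceeds rank %d; truncated", n_components, rank)
        n_components = max(rank, 1)
    scores = U[:, :n_components] * s[:n_components]
    return BiplotCoordinates(list(a.ids), scores, frac)
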
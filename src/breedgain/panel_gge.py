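"""Elite-panel selection and GGE stability analysis.

The elite panel keeps genotypes whose breeding value and reliability both
strictly exceed their thresholds, sorted by breeding value (optionally
truncated to the best ``top_n`` with deterministic tie-breaking).

Stability of a genotype x environment mean table follows the GGE biplot
construction: each environment's mean is subtracted (tester-centred G+GE),
no scaling, and the SVD is taken with row metric preserving — genotype
scores U*S, environment scores V.  The average-environment axis is the
direction of the mean environment score; the ideal genotype sits on that
axis at the largest genotype projection; genotypes are ranked by Euclidean
distance (PC1-PC2) from that ideal point.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("breedgain")


class DegenerateTableError(ValueError):
    pass


@dataclass
class ElitePanel:
    selected: pd.DataFrame     # genotype, breeding_value, reliability, ...
    bv_threshold: float
    reliability_threshold: float
    top_n: Optional[int] = None

    def __len__(self) -> int:
        return len(self.selected)


def select_elite(stage2_table: pd.DataFrame, bv_threshold: float,
                 rel_threshold: float = 0.4,
                 top_n: Optional[int] = None) -> ElitePanel:
    """Strict-inequality filter on breeding value and reliability.

    Survivors are sorted by descending breeding value; with ``top_n`` set,
    ties at the truncation boundary break by higher reliability, then
    lexicographic genotype id, so the panel is deterministic and invariant
    to input row order.
    """
    t = stage2_table
    mask = (t["breeding_value"] > bv_threshold) & (t["reliability"] > rel_threshold)
    sel = t.loc[mask].copy()
    sel["genotype"] = sel["genotype"].astype(str)
    sel = sel.sort_values(
        by=["breeding_value", "reliability", "genotype"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if top_n is not None:
        sel = sel.head(int(top_n)).reset_index(drop=True)
    if sel.empty:
        logger.warning("elite panel is empty at bv > %g, rel > %g",
                       bv_threshold, rel_threshold)
    return ElitePanel(selected=sel, bv_threshold=bv_threshold,
                      reliability_threshold=rel_threshold, top_n=top_n)


@dataclass
class GGEResult:
    genotypes: list
    environments: list
    genotype_scores: np.ndarray      # (n_g, k) = U * S, row metric preserving
    environment_scores: np.ndarray   # (n_e, k) = V
    pc_variance_pct: np.ndarray
    mean_environment_axis: np.ndarray  # unit direction in PC1-PC2
    ideal_point: np.ndarray            # in PC1-PC2
    stability_rank: pd.DataFrame       # genotype, distance, rank
    centered: np.ndarray = field(repr=False, default=None)


def gge_analysis(ge_means: pd.DataFrame) -> GGEResult:
    """GGE decomposition of a complete genotype x environment mean table.

    Rows are genotypes, columns environments (kg/ha).  Missing cells are
    rejected; a table that is constant after environment-centring raises
    :class:`DegenerateTableError`.
    """
    if ge_means.shape[0] < 3 or ge_means.shape[1] < 2:
        raise ValueError("need >= 3 genotypes and >= 2 environments")
    X = ge_means.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("genotype x environment table has missing cells")
    centered = X - X.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0.0):
        raise DegenerateTableError("table constant after environment centring")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    gscores = U * s
    escores = Vt.T
    pct = 100.0 * s**2 / np.sum(s**2)
    mean_env = escores[:, :2].mean(axis=0)
    norm = np.linalg.norm(mean_env)
    if norm == 0:
        raise DegenerateTableError("mean environment direction undefined")
    axis = mean_env / norm
    proj = gscores[:, :2] @ axis
    ideal = axis * proj.max()
    dist = np.linalg.norm(gscores[:, :2] - ideal[None, :], axis=1)
    order = np.argsort(dist, kind="stable")
    rank = np.empty(len(dist), dtype=int)
    rank[order] = np.arange(1, len(dist) + 1)
    stability = pd.DataFrame({
        "genotype": list(ge_means.index),
        "distance_to_ideal": dist,
        "stability_rank": rank,
    }).sort_values("stability_rank").reset_index(drop=True)
    return GGEResult(
        genotypes=list(ge_means.index),
        environments=list(ge_means.columns),
        genotype_scores=gscores,
        environment_scores=escores,
        pc_variance_pct=pct,
        mean_environment_axis=axis,
        ideal_point=ideal,
        stability_rank=stability,
        centered=centered,
    )


def rank_report(gge: GGEResult, panel: ElitePanel,
                stage2_table: Optional[pd.DataFrame] = None,
                path=None) -> pd.DataFrame:
    """Merge stability ranks with panel membership and breeding values.

    Genotypes in the GGE table missing from stage 2 are listed with missing
    breeding values rather than raising.  Optionally serialised to CSV
    (``path``.csv) and JSON (``path``.json).
    """
    out = gge.stability_rank.copy()
    source = stage2_table if stage2_table is not None else panel.selected
    if source is not None and len(source):
        bv = source.set_index("genotype")[["breeding_value", "reliability"]]
        out = out.join(bv, on="genotype")
    else:
        out["breeding_value"] = np.nan
        out["reliability"] = np.nan
    out["in_panel"] = out["genotype"].isin(set(panel.selected["genotype"]))
    if path is not None:
        path = Path(path)
        out.to_csv(path.with_suffix(".csv"), index=False)
        path.with_suffix(".json").write_text(
            json.dumps(out.to_dict(orient="records"), indent=1, default=str))
    return out
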
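"""Synthetic breeding-program generator.

Emulates a multi-year crossing program followed by multi-environment yield
trials, with known ground truth, so the whole two-stage analysis can be
exercised and scored without external data:

* a pedigree grown over 10-15 crossing years from a founder set, using
  single, double, three-way, complex and backcrosses (double/three-way/
  complex crosses are decomposed into chains of intermediate single crosses
  so every entry has exactly two parent slots);
* additive genetic values following the pedigree: founders N(0, s2_g),
  offspring = parental mean + Mendelian sampling N(0, 0.5*s2_g*(1-Fbar))
  with Fbar the mean parental inbreeding from the relationship-matrix
  diagonal; parents each year are chosen by truncation selection on true
  value, so an upward genetic trend is *realized*, not imposed;
* trials over consecutive years x two seasons under RCBD, augmented RCBD,
  alpha-lattice and row-column designs, with a common set of checks in
  every trial (connectivity), per-trial error variances drawn log-uniform
  (heterogeneity), a days-to-flowering covariate effect, missingness, and
  recorded additive outlier contamination.

True breeding values are reported on the phenotypic scale (baseline mean +
genetic deviation), matching how estimated breeding values are reported
downstream; the ground-truth trend is the realized OLS slope of true value
on year of origin over primary entries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("breedgain")

CROSS_TYPES = ["single", "double", "three_way", "complex", "backcross"]
DESIGNS = ["rcbd", "augmented_rcbd", "alpha_lattice", "row_column"]

PHENOTYPE_COLUMNS = [
    "genotype", "year", "season", "location", "design",
    "rep", "block", "row", "col", "yield_kg_ha", "dtf",
]
PEDIGREE_COLUMNS = [
    "genotype", "parent_f", "parent_m", "year_of_origin",
    "cross_type", "year_of_release", "is_primary",
]


class InvalidConfigError(ValueError):
    pass


class LayoutError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic breeding program.

    Defaults describe a modest stress-breeding program: ~200 kg/ha genetic
    SD around a 3000 kg/ha baseline (salinity-stressed yields), strongly
    heterogeneous trial error, two seasons per year, and four rotating
    experimental designs.
    """

    n_founders: int = 40
    n_years_crossing: int = 10
    crosses_per_year: int = 30
    cross_type_mix: dict = field(default_factory=lambda: {
        "single": 0.55, "double": 0.10, "three_way": 0.15,
        "complex": 0.10, "backcross": 0.10,
    })
    selection_fraction: float = 0.2
    sigma2_g: float = 40_000.0          # (kg/ha)^2, genetic SD 200
    sigma2_e_range: tuple = (60_000.0, 250_000.0)
    mu_yield: float = 3000.0            # kg/ha baseline
    dtf_mean: float = 95.0              # days
    dtf_sd: float = 8.0
    beta_dtf: float = -15.0             # kg/ha per day
    n_trial_years: int = 10
    designs: tuple = tuple(DESIGNS)
    n_checks: int = 4
    missing_rate: float = 0.05
    outlier_rate: float = 0.01
    outlier_shift_sd: float = 8.0       # multiples of trial error SD
    seed: int = 0
    # nuisance-effect variances, recorded in the run log
    sigma2_env: float = 90_000.0        # year-season environment
    sigma2_rep: float = 10_000.0
    sigma2_block: float = 10_000.0
    sigma2_rowcol: float = 5_000.0
    entries_per_trial: int = 100        # incl. checks; trial sizes are not a claim
    n_seasons: int = 2
    first_year: int = 2008
    trial_start_offset: int = 3

    def validate(self) -> None:
        if self.n_founders < 2:
            raise InvalidConfigError("need at least 2 founders")
        if self.n_years_crossing > 0 and self.crosses_per_year == 0:
            raise InvalidConfigError("crosses_per_year = 0 with crossing years requested")
        if self.sigma2_g < 0 or any(v < 0 for v in self.sigma2_e_range):
            raise InvalidConfigError("variances must be non-negative")
        if self.sigma2_e_range[0] > self.sigma2_e_range[1]:
            raise InvalidConfigError("sigma2_e_range must be (low, high)")
        mix_sum = sum(self.cross_type_mix.values())
        if abs(mix_sum - 1.0) > 1e-8:
            raise InvalidConfigError(f"cross_type_mix sums to {mix_sum}, not 1")
        if set(self.cross_type_mix) - set(CROSS_TYPES):
            raise InvalidConfigError("unknown cross type in mix")
        for p in (self.selection_fraction, self.missing_rate, self.outlier_rate):
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError("proportions must be in [0, 1]")
        if self.n_checks < 2:
            raise InvalidConfigError("n_checks must be >= 2 for connectivity")
        if set(self.designs) - set(DESIGNS):
            raise InvalidConfigError("unknown design requested")


@dataclass
class TruthSet:
    true_bv: dict                    # genotype -> kg/ha (baseline + deviation)
    realized_trend_slope: float      # kg/ha per year of origin, OLS on primary entries
    realized_trend_percent: float    # 100 * slope / mean(true_bv)
    outlier_ids: list = field(default_factory=list)  # row positions in phenotype table

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "true_bv": self.true_bv,
            "realized_trend_slope": self.realized_trend_slope,
            "realized_trend_percent": self.realized_trend_percent,
            "outlier_ids": self.outlier_ids,
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        return cls(d["true_bv"], d["realized_trend_slope"],
                   d["realized_trend_percent"], d["outlier_ids"])


# ---------------------------------------------------------------------------
# pedigree + true values (co-simulated: selection acts on true values)
# ---------------------------------------------------------------------------

def _select_parents(rng, pool, values, fraction, k):
    """Truncation selection: top `fraction` of pool by value, sample k."""
    ranked = sorted(pool, key=lambda g: -values[g])
    n_top = max(2, int(np.ceil(fraction * len(ranked))))
    top = ranked[:n_top]
    idx = rng.choice(len(top), size=k, replace=len(top) < k)
    return [top[i] for i in idx]


class _Grower:
    """Incrementally grown pedigree with relationship-matrix bookkeeping."""

    def __init__(self, capacity: int, sigma2_g: float, rng):
        self.A = np.zeros((capacity, capacity))
        self.index: dict = {}
        self.rows: list = []
        self.g: dict = {}  # genetic deviation
        self.sigma2_g = sigma2_g
        self.rng = rng

    def add(self, gid, pf, pm, year, cross_type, is_primary):
        i = len(self.rows)
        s = self.index.get(pf)
        d = self.index.get(pm)
        if i:
            row = np.zeros(i)
            if s is not None:
                row += 0.5 * self.A[s, :i]
            if d is not None:
                row += 0.5 * self.A[d, :i]
            self.A[i, :i] = row
            self.A[:i, i] = row
        a_sd = self.A[s, d] if (s is not None and d is not None) else 0.0
        self.A[i, i] = 1.0 + 0.5 * a_sd
        if s is None and d is None:
            value = self.rng.normal(0.0, np.sqrt(self.sigma2_g))
        else:
            vs = self.g[pf] if s is not None else 0.0
            vd = self.g[pm] if d is not None else 0.0
            f_s = self.A[s, s] - 1.0 if s is not None else 0.0
            f_d = self.A[d, d] - 1.0 if d is not None else 0.0
            ms_var = 0.5 * self.sigma2_g * (1.0 - 0.5 * (f_s + f_d))
            value = 0.5 * (vs + vd) + self.rng.normal(0.0, np.sqrt(max(ms_var, 0.0)))
        self.index[gid] = i
        self.g[gid] = value
        self.rows.append({
            "genotype": gid, "parent_f": pf, "parent_m": pm,
            "year_of_origin": year, "cross_type": cross_type,
            "year_of_release": np.nan, "is_primary": is_primary,
        })


def _cosimulate(config: SimConfig):
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    cap = config.n_founders + config.n_years_crossing * config.crosses_per_year * 4 + 8
    grow = _Grower(cap, config.sigma2_g, rng)
    y0 = config.first_year
    founders = [f"F{i + 1:03d}" for i in range(config.n_founders)]
    for gid in founders:
        grow.add(gid, None, None, y0, "founder", True)

    types = list(config.cross_type_mix)
    probs = np.array([config.cross_type_mix[t] for t in types], dtype=float)
    probs /= probs.sum()
    for t in range(1, config.n_years_crossing + 1):
        year = y0 + t
        primary = [r for r in grow.rows if r["is_primary"]]
        pool1 = [r["genotype"] for r in primary if r["year_of_origin"] < year]
        pool2 = [r["genotype"] for r in primary if r["year_of_origin"] < year - 1]
        pool3 = [r["genotype"] for r in primary if r["year_of_origin"] < year - 2]
        for k in range(config.crosses_per_year):
            ct = types[rng.choice(len(types), p=probs)]
            if ct in ("double", "three_way") and len(pool2) < 2:
                ct = "single"
            if ct == "complex" and len(pool3) < 2:
                ct = "three_way" if len(pool2) >= 2 else "single"
            gid = f"C{year}_{k + 1:03d}"
            if ct == "backcross":
                nonf = [g for g in pool1
                        if grow.rows[grow.index[g]]["parent_f"] is not None]
                if not nonf:
                    ct = "single"
            if ct == "single":
                p1, p2 = _select_parents(rng, pool1, grow.g,
                                         config.selection_fraction, 2)
                grow.add(gid, p1, p2, year, "single", True)
            elif ct == "backcross":
                x = _select_parents(rng, nonf, grow.g, config.selection_fraction, 1)[0]
                entry = grow.rows[grow.index[x]]
                back = entry["parent_f"] if rng.integers(2) else entry["parent_m"]
                if back is None:
                    back = entry["parent_f"] or entry["parent_m"]
                grow.add(gid, x, back, year, "backcross", True)
            elif ct == "three_way":
                a, b = _select_parents(rng, pool2, grow.g,
                                       config.selection_fraction, 2)
                i1 = f"I{year}_{k + 1:03d}a"
                grow.add(i1, a, b, year - 1, "single", False)
                c = _select_parents(rng, pool1, grow.g, config.selection_fraction, 1)[0]
                grow.add(gid, i1, c, year, "three_way", True)
            elif ct == "double":
                a, b = _select_parents(rng, pool2, grow.g, config.selection_fraction, 2)
                c, d = _select_parents(rng, pool2, grow.g, config.selection_fraction, 2)
                i1 = f"I{year}_{k + 1:03d}a"
                i2 = f"I{year}_{k + 1:03d}b"
                grow.add(i1, a, b, year - 1, "single", False)
                grow.add(i2, c, d, year - 1, "single", False)
                grow.add(gid, i1, i2, year, "double", True)
            else:  # complex: ((a x b) x c) x d over three years
                a, b = _select_parents(rng, pool3, grow.g, config.selection_fraction, 2)
                i1 = f"I{year}_{k + 1:03d}a"
                grow.add(i1, a, b, year - 2, "single", False)
                c = _select_parents(rng, pool2, grow.g, config.selection_fraction, 1)[0]
                i2 = f"I{year}_{k + 1:03d}b"
                grow.add(i2, i1, c, year - 1, "single", False)
                d = _select_parents(rng, pool1, grow.g, config.selection_fraction, 1)[0]
                grow.add(gid, i2, d, year, "complex", True)

    ped = pd.DataFrame(grow.rows, columns=PEDIGREE_COLUMNS)
    # releases: the best genotype of each origin cohort, released 4 years on
    primary = ped[ped["is_primary"]]
    for year, grp in primary.groupby("year_of_origin"):
        best = max(grp["genotype"], key=lambda g: grow.g[g])
        ped.loc[ped["genotype"] == best, "year_of_release"] = year + 4
    true_bv = {g: config.mu_yield + v for g, v in grow.g.items()}
    return ped, true_bv


def _realized_trend(ped: pd.DataFrame, true_bv: dict):
    primary = ped[ped["is_primary"]]
    years = primary["year_of_origin"].to_numpy(dtype=float)
    vals = np.array([true_bv[g] for g in primary["genotype"]])
    if len(set(years)) < 2 or np.ptp(vals) == 0:
        slope = 0.0
    else:
        slope = float(np.polyfit(years, vals, 1)[0])
    mean_bv = float(np.mean(vals))
    percent = 100.0 * slope / mean_bv if mean_bv != 0 else 0.0
    return slope, percent


def simulate_pedigree(config: SimConfig) -> pd.DataFrame:
    """Grow a pedigree by seeded truncation-selection crossing.

    Founders carry unknown parents and the first year of origin; every
    non-founder's parents exist with a strictly earlier year of origin.
    Multi-parent crosses appear as chains of intermediate single crosses
    (``is_primary = False``).
    """
    ped, _ = _cosimulate(config)
    return ped


def simulate_true_values(pedigree: pd.DataFrame, config: SimConfig) -> TruthSet:
    """Ground-truth additive values for a pedigree.

    For a pedigree produced by :func:`simulate_pedigree` with the same
    config, the co-simulated values (on which parental selection acted) are
    returned, so identical seeds reproduce identical truth.  For any other
    pedigree, values are dropped down the given structure without selection.
    """
    ped, true_bv = _cosimulate(config)
    same = (
        len(ped) == len(pedigree)
        and list(ped["genotype"]) == list(pedigree["genotype"])
    )
    if not same:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
        grow = _Grower(len(pedigree) + 1, config.sigma2_g, rng)
        for _, r in pedigree.iterrows():
            pf = r["parent_f"] if pd.notna(r["parent_f"]) else None
            pm = r["parent_m"] if pd.notna(r["parent_m"]) else None
            grow.add(r["genotype"], pf, pm, r.get("year_of_origin", 0),
                     r.get("cross_type", "single"), bool(r.get("is_primary", True)))
        true_bv = {g: config.mu_yield + v for g, v in grow.g.items()}
        ped = pedigree
    slope, percent = _realized_trend(ped, true_bv)
    return TruthSet(true_bv, slope, percent)


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

def _layout(rng, design, genos, checks):
    """Plot list [(genotype, rep, block, row, col)] for one trial."""
    n = len(genos)
    if n < 2:
        raise LayoutError(f"design {design!r} needs >= 2 genotypes, got {n}")
    plots = []
    if design == "rcbd":
        for rep in (1, 2):
            for g in rng.permutation(genos):
                plots.append((g, str(rep), str(rep), None, None))
    elif design == "augmented_rcbd":
        entries = [g for g in genos if g not in checks]
        n_blocks = 4
        assign = rng.integers(0, n_blocks, size=len(entries))
        for b in range(n_blocks):
            for g in checks:
                plots.append((g, "1", str(b + 1), None, None))
            for g, gb in zip(entries, assign):
                if gb == b:
                    plots.append((g, "1", str(b + 1), None, None))
    elif design == "alpha_lattice":
        n_blocks = max(2, int(round(np.sqrt(n))))
        if n < n_blocks:
            raise LayoutError(f"alpha lattice needs >= {n_blocks} genotypes")
        for rep in (1, 2):
            perm = rng.permutation(genos)
            for j, g in enumerate(perm):
                b = j % n_blocks
                plots.append((g, str(rep), f"{rep}-{b + 1}", None, None))
    elif design == "row_column":
        nr = max(2, int(np.ceil(np.sqrt(n))))
        for rep in (1, 2):
            perm = rng.permutation(genos)
            for j, g in enumerate(perm):
                r, c = divmod(j, nr)
                plots.append((g, str(rep), None, f"{rep}-{r + 1}", f"{rep}-{c + 1}"))
    else:
        raise LayoutError(f"unknown design {design!r}")
    return plots


def _log_uniform(rng, lo, hi):
    if lo == hi:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def simulate_trials(pedigree: pd.DataFrame, truth: TruthSet,
                    config: SimConfig) -> pd.DataFrame:
    """Simulate the multi-year trial phenotypes.

    Each trial year x season tests a sample of recent primary genotypes plus
    every check under one of the configured designs.  An observation is
    baseline-inclusive true value + year-season environment + design-factor
    effects + DTF covariate effect + trial-specific error; missingness and
    recorded outlier shifts are applied last.  Outlier row positions are
    stored in ``truth.outlier_ids``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    ped = pedigree
    primary = ped[ped["is_primary"]] if "is_primary" in ped.columns else ped
    founders = [g for g in ped["genotype"]
                if str(g).startswith("F")][: config.n_checks]
    if len(founders) < config.n_checks:
        founders = list(ped["genotype"][: config.n_checks])
    checks = founders
    missing_bv = [g for g in ped["genotype"] if g not in truth.true_bv]
    if missing_bv:
        raise ValueError(f"genotypes without true values: {missing_bv[:5]}")

    dtf_base = {g: rng.normal(config.dtf_mean, config.dtf_sd)
                for g in ped["genotype"]}
    seasons = ["DS", "WS"][: config.n_seasons]
    rows = []
    err_sds = []
    y0 = config.first_year + config.trial_start_offset
    for ty in range(y0, y0 + config.n_trial_years):
        env_year = {s: rng.normal(0.0, np.sqrt(config.sigma2_env)) for s in seasons}
        for season in seasons:
            recent = primary[(primary["year_of_origin"] <= ty)
                             & (primary["year_of_origin"] > ty - 5)]
            cands = [g for g in recent["genotype"] if g not in checks]
            if len(cands) < 4:
                older = primary[primary["year_of_origin"] <= ty]
                cands = [g for g in older["genotype"] if g not in checks]
            n_entries = min(config.entries_per_trial - config.n_checks, len(cands))
            entries = list(rng.choice(cands, size=n_entries, replace=False)) \
                if n_entries else []
            genos = checks + entries
            design = config.designs[rng.integers(len(config.designs))]
            plots = _layout(rng, design, genos, set(checks))
            err_sd = np.sqrt(_log_uniform(rng, *config.sigma2_e_range))
            rep_eff, blk_eff, row_eff, col_eff = {}, {}, {}, {}
            for g, rep, blk, r, c in plots:
                for key, eff, s2 in ((rep, rep_eff, config.sigma2_rep),
                                     (blk, blk_eff, config.sigma2_block),
                                     (r, row_eff, config.sigma2_rowcol),
                                     (c, col_eff, config.sigma2_rowcol)):
                    if key is not None and key not in eff:
                        eff[key] = rng.normal(0.0, np.sqrt(s2))
                dtf = max(40, int(round(dtf_base[g] + rng.normal(0.0, 2.0))))
                y = (truth.true_bv[g]
                     + env_year[season]
                     + (rep_eff.get(rep, 0.0) if rep else 0.0)
                     + (blk_eff.get(blk, 0.0) if blk else 0.0)
                     + (row_eff.get(r, 0.0) if r else 0.0)
                     + (col_eff.get(c, 0.0) if c else 0.0)
                     + config.beta_dtf * (dtf - config.dtf_mean)
                     + rng.normal(0.0, err_sd))
                rows.append({
                    "genotype": g, "year": ty, "season": season,
                    "location": "STN", "design": design,
                    "rep": rep, "block": blk, "row": r, "col": c,
                    "yield_kg_ha": max(y, 0.0), "dtf": dtf,
                })
                err_sds.append(err_sd)
    table = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
    err_sds = np.array(err_sds)

    n = len(table)
    miss = rng.random(n) < config.missing_rate
    table.loc[miss, "yield_kg_ha"] = np.nan
    outlier_mask = (rng.random(n) < config.outlier_rate) & ~miss
    signs = rng.choice([-1.0, 1.0], size=n)
    shift = signs * config.outlier_shift_sd * err_sds
    table.loc[outlier_mask, "yield_kg_ha"] = (
        table.loc[outlier_mask, "yield_kg_ha"] + shift[outlier_mask]
    ).clip(lower=0.0)
    truth.outlier_ids = [int(i) for i in np.flatnonzero(outlier_mask)]
    logger.info("simulated %d plots over %d trials (%d outliers injected)",
                n, table.groupby(["year", "season", "location"]).ngroups,
                len(truth.outlier_ids))
    return table


def simulate_program(config: SimConfig):
    """Full co-simulation: (pedigree, truth, phenotypes)."""
    ped = simulate_pedigree(config)
    truth = simulate_true_values(ped, config)
    pheno = simulate_trials(ped, truth, config)
    return ped, truth, pheno


def write_run(outdir, pedigree: pd.DataFrame, truth: TruthSet,
              phenotypes: pd.DataFrame) -> None:
    """Write phenotypes.csv, pedigree.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    pedigree.to_csv(outdir / "pedigree.csv", index=False)
    truth.to_json(outdir / "truth.json")
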
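"""Mixed-model engine: design construction, REML, MME solutions."""

import numpy as np
import pandas as pd
import pytest

import breedgain as bg
from breedgain.lmm_core import _mme_pieces, _neg2_reml, _term_structures


@pytest.fixture
def rng():
    return np.random.default_rng(42)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def test_intercept_only_design():
    df = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
    dm = bg.build_design(df, bg.ModelSpec(response="y"))
    assert dm.X.shape == (3, 1)
    assert np.all(dm.X == 1.0)


def test_factor_treatment_coding_k_minus_one():
    df = pd.DataFrame({"y": np.arange(9.0), "f": list("abcabcabc")})
    dm = bg.build_design(df, bg.ModelSpec(response="y", fixed=["f"]))
    assert dm.X.shape[1] == 1 + 2  # intercept + (k-1)
    assert dm.factor_columns["f"]["a"] is None  # first observed = reference


def test_alpha_lattice_incidence_blocks():
    # 3 reps x 4 blocks nested in rep: 12 block levels, 3 rep levels
    rows = []
    for rep in range(3):
        for blk in range(4):
            for plot in range(2):
                rows.append({"y": 1.0, "rep": str(rep), "blk": f"{rep}-{blk}"})
    df = pd.DataFrame(rows)
    dm = bg.build_design(df, bg.ModelSpec(
        response="y", random=[bg.RandomTerm("rep"), bg.RandomTerm("blk")]))
    assert dm.Z[0].shape == (24, 3)
    assert dm.Z[1].shape == (24, 12)
    # each row hits exactly one rep and one block
    assert np.all(dm.Z[0].sum(axis=1) == 1)
    assert np.all(dm.Z[1].sum(axis=1) == 1)
    # block incidence nests within rep incidence
    for j, lev in enumerate(dm.random_levels[1]):
        rep_of_block = lev.split("-")[0]
        i = dm.random_levels[0].index(rep_of_block)
        assert np.all(dm.Z[0][dm.Z[1][:, j] == 1, i] == 1)


def test_constant_covariate_removed():
    df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [5.0, 5.0, 5.0]})
    dm = bg.build_design(df, bg.ModelSpec(response="y", fixed=["x"]))
    assert "x" not in dm.fixed_names
    assert any("constant" in line for line in dm.log)


def test_missing_rows_dropped_and_logged():
    df = pd.DataFrame({"y": [1.0, np.nan, 3.0], "x": [1.0, 2.0, np.nan]})
    dm = bg.build_design(df, bg.ModelSpec(response="y", fixed=["x"]))
    assert dm.X.shape[0] == 1
    assert list(dm.rows_kept) == [0]


def test_term_cannot_be_both_fixed_and_random():
    with pytest.raises(ValueError, match="both fixed and random"):
        bg.ModelSpec(response="y", fixed=["f"], random=[bg.RandomTerm("f")])


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def test_reml_equals_anova_balanced_one_way(rng):
    g, r = 15, 4
    df = pd.DataFrame({"grp": np.repeat([f"g{i}" for i in range(g)], r)})
    df["y"] = (rng.normal(0, 2, g)[np.repeat(np.arange(g), r)]
               + rng.normal(size=g * r))
    dm = bg.build_design(df, bg.ModelSpec(response="y",
                                          random=[bg.RandomTerm("grp")]))
    vc = bg.reml_fit(dm)
    ybar = df.groupby("grp")["y"].mean()
    mse = ((df["y"] - ybar.loc[df["grp"]].to_numpy())**2).sum() / (g * r - g)
    msb = r * ((ybar - df["y"].mean())**2).sum() / (g - 1)
    assert vc.converged
    assert vc.sigma2["residual"] == pytest.approx(mse, rel=1e-6)
    assert vc.sigma2["grp"] == pytest.approx((msb - mse) / r, rel=1e-6)


def test_reml_zero_within_group_variance_clamps():
    df = pd.DataFrame({"grp": list("aabbcc"), "y": [1.0, 1, 2, 2, 3, 3]})
    dm = bg.build_design(df, bg.ModelSpec(response="y",
                                          random=[bg.RandomTerm("grp")]))
    vc = bg.reml_fit(dm)
    assert "residual" in vc.clamped


def test_reml_simulation_recovery(rng):
    """Mean REML estimates across seeds recover the generating components."""
    s2g_true, s2e_true = 40_000.0, 90_000.0
    g, r = 50, 10  # n = 500
    est_g, est_e = [], []
    for _ in range(100):
        gv = rng.normal(0, np.sqrt(s2g_true), g)
        df = pd.DataFrame({"grp": np.repeat([f"g{i}" for i in range(g)], r)})
        df["y"] = gv[np.repeat(np.arange(g), r)] + rng.normal(
            0, np.sqrt(s2e_true), g * r)
        dm = bg.build_design(df, bg.ModelSpec(response="y",
                                              random=[bg.RandomTerm("grp")]))
        vc = bg.reml_fit(dm)
        est_g.append(vc.sigma2["grp"])
        est_e.append(vc.sigma2["residual"])
    assert np.mean(est_g) == pytest.approx(s2g_true, rel=0.05)
    assert np.mean(est_e) == pytest.approx(s2e_true, rel=0.05)


def test_reml_loglik_invariant_to_fixed_coding(rng):
    df = pd.DataFrame({"grp": np.repeat(list("abcd"), 6),
                       "f": rng.choice(list("xyz"), 24)})
    df["y"] = rng.normal(size=24)
    dms = [
        bg.build_design(df, bg.ModelSpec(response="y", fixed=["f"],
                                         random=[bg.RandomTerm("grp")])),
        bg.build_design(df, bg.ModelSpec(response="y", fixed=["f"],
                                         random=[bg.RandomTerm("grp")],
                                         cell_means="f")),
    ]
    theta = np.log([0.7, 1.3])
    vals = []
    for dm in dms:
        Kinvs, Klogdets = _term_structures(dm)
        _, A0, r0, yy = _mme_pieces(dm)
        vals.append(_neg2_reml(theta, A0, r0, yy, dm, Kinvs, Klogdets))
    assert vals[0] == pytest.approx(vals[1], abs=1e-8)


# ---------------------------------------------------------------------------
# MME solutions
# ---------------------------------------------------------------------------

def test_mme_no_random_equals_wls(rng):
    n = 40
    df = pd.DataFrame({"x": rng.normal(size=n), "f": rng.choice(list("abc"), n),
                       "w": rng.uniform(0.5, 2, n)})
    df["y"] = 1 + 2 * df.x + rng.normal(size=n)
    dm = bg.build_design(df, bg.ModelSpec(response="y", fixed=["x", "f"],
                                          weights="w"))
    vc = bg.VarianceComponents(sigma2={"residual": 1.3}, converged=True,
                               n_iterations=0, reml_loglik=0.0)
    fit = bg.solve_mme(dm, vc)
    W = np.diag(dm.weights)
    beta = np.linalg.solve(dm.X.T @ W @ dm.X, dm.X.T @ W @ dm.y)
    assert np.abs(fit.beta - beta).max() < 1e-10


def test_mme_balanced_blup_shrinkage_closed_form(rng):
    g, r = 12, 5
    df = pd.DataFrame({"grp": np.repeat([f"g{i}" for i in range(g)], r)})
    df["y"] = (rng.normal(0, 2, g)[np.repeat(np.arange(g), r)]
               + rng.normal(size=g * r))
    s2g, s2e = 4.0, 1.0
    dm = bg.build_design(df, bg.ModelSpec(response="y",
                                          random=[bg.RandomTerm("grp")]))
    vc = bg.VarianceComponents(sigma2={"grp": s2g, "residual": s2e},
                               converged=True, n_iterations=0, reml_loglik=0.0)
    fit = bg.solve_mme(dm, vc)
    lam = s2e / s2g
    ybar = df.groupby("grp", sort=False)["y"].mean()
    expected = (ybar.loc[fit.random_levels["grp"]].to_numpy()
                - df["y"].mean()) * r / (r + lam)
    assert np.abs(fit.u["grp"] - expected).max() < 1e-10


def test_unrecorded_genotype_predicted_through_relationships():
    ped = pd.DataFrame({
        "genotype": ["P1", "P2", "kid", "ghost"],
        "parent_f": [None, None, "P1", "P1"],
        "parent_m": [None, None, "P2", "P2"],
    })
    a = bg.build_a_matrix(ped)
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "g": np.repeat(["P1", "P2", "kid"], 5),
        "y": np.repeat([3.0, -1.0, 1.5], 5) + rng.normal(0, 0.3, 15),
    })
    term = bg.RandomTerm("g", covariance=a.values, levels=a.ids)
    dm = bg.build_design(df, bg.ModelSpec(response="y", random=[term]))
    s2g = 2.0
    vc = bg.VarianceComponents(sigma2={"g": s2g, "residual": 0.5},
                               converged=True, n_iterations=0, reml_loglik=0.0)
    fit = bg.solve_mme(dm, vc)
    i = fit.random_levels["g"].index("ghost")
    assert np.isfinite(fit.u["g"][i]) and fit.u["g"][i] != 0.0
    assert fit.pev["g"][i] < s2g * a.values[a.index["ghost"], a.index["ghost"]]


def test_pev_bounded_by_prior_variance(small_stage2, small_amatrix):
    t = small_stage2.table
    assert np.all(t["pev"] <= t["prior_variance"] + 1e-8)


def test_scale_equivariance_weights_vs_residual(rng):
    """R = s2_e / w: rescaling weights and s2_e together leaves the
    residual covariance, hence all predictions, unchanged."""
    n, g = 60, 10
    df = pd.DataFrame({"grp": rng.choice([f"g{i}" for i in range(g)], n),
                       "w": rng.uniform(0.5, 2.0, n)})
    df["y"] = rng.normal(size=n)
    dm1 = bg.build_design(df, bg.ModelSpec(response="y", weights="w",
                                           random=[bg.RandomTerm("grp")]))
    df2 = df.assign(w=2 * df["w"])
    dm2 = bg.build_design(df2, bg.ModelSpec(response="y", weights="w",
                                            random=[bg.RandomTerm("grp")]))
    vc1 = bg.VarianceComponents(sigma2={"grp": 1.7, "residual": 0.9},
                                converged=True, n_iterations=0, reml_loglik=0.0)
    vc2 = bg.VarianceComponents(sigma2={"grp": 1.7, "residual": 1.8},
                                converged=True, n_iterations=0, reml_loglik=0.0)
    f1, f2 = bg.solve_mme(dm1, vc1), bg.solve_mme(dm2, vc2)
    assert np.abs(f1.beta - f2.beta).max() < 1e-10
    assert np.abs(f1.u["grp"] - f2.u["grp"]).max() < 1e-10
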
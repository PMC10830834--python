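"""Elite-panel selection and GGE stability geometry."""

import numpy as np
import pandas as pd
import pytest

import breedgain as bg
from breedgain.panel_gge import DegenerateTableError


def _stage2_frame(rng, n=200):
    return pd.DataFrame({
        "genotype": [f"g{i:04d}" for i in range(n)],
        "breeding_value": rng.normal(3000, 400, n).round(1),
        "reliability": rng.uniform(0, 1, n).round(3),
    })


def test_thresholds_below_all_selects_everything_sorted():
    rng = np.random.default_rng(0)
    t = _stage2_frame(rng, 50)
    panel = bg.select_elite(t, bv_threshold=-1e9, rel_threshold=-1.0)
    assert len(panel) == 50
    bv = panel.selected["breeding_value"].to_numpy()
    assert np.all(np.diff(bv) <= 0)


def test_threshold_above_max_gives_empty_panel():
    rng = np.random.default_rng(1)
    t = _stage2_frame(rng, 30)
    panel = bg.select_elite(t, bv_threshold=t["breeding_value"].max() + 1)
    assert len(panel) == 0


def test_strict_inequality_at_threshold():
    t = pd.DataFrame({"genotype": ["a", "b"],
                      "breeding_value": [2300.0, 2300.1],
                      "reliability": [0.4, 0.41]})
    panel = bg.select_elite(t, bv_threshold=2300.0, rel_threshold=0.4)
    assert list(panel.selected["genotype"]) == ["b"]


def test_selection_row_order_invariant():
    rng = np.random.default_rng(2)
    t = _stage2_frame(rng, 100)
    p1 = bg.select_elite(t, 3000.0, 0.4, top_n=20)
    p2 = bg.select_elite(t.sample(frac=1.0, random_state=5), 3000.0, 0.4,
                         top_n=20)
    assert list(p1.selected["genotype"]) == list(p2.selected["genotype"])


def test_tie_breaking_at_truncation_boundary():
    t = pd.DataFrame({
        "genotype": ["z", "a", "m"],
        "breeding_value": [3000.0, 3000.0, 3000.0],
        "reliability": [0.5, 0.5, 0.9],
    })
    panel = bg.select_elite(t, 0.0, 0.4, top_n=2)
    # higher reliability first, then lexicographic id
    assert list(panel.selected["genotype"]) == ["m", "a"]


def test_rank_one_table_pc1_explains_all():
    g = np.array([5.0, 1.0, -2.0, 0.0])
    table = pd.DataFrame(np.outer(g, np.ones(4)) + np.array([1.0, 2, 3, 4]),
                         index=list("abcd"), columns=list("wxyz"))
    res = bg.gge_analysis(table)
    assert res.pc_variance_pct[0] == pytest.approx(100.0, abs=1e-9)


def test_full_svd_reconstruction():
    rng = np.random.default_rng(3)
    table = pd.DataFrame(rng.normal(3000, 300, (8, 5)),
                         index=[f"g{i}" for i in range(8)],
                         columns=[f"e{j}" for j in range(5)])
    res = bg.gge_analysis(table)
    recon = res.genotype_scores @ res.environment_scores.T
    assert np.abs(recon - res.centered).max() < 1e-8


def test_missing_cells_rejected():
    table = pd.DataFrame(np.ones((4, 3)), index=list("abcd"),
                         columns=list("xyz"))
    table.iloc[1, 2] = np.nan
    with pytest.raises(ValueError, match="missing"):
        bg.gge_analysis(table)


def test_degenerate_table_error():
    table = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (4, 1)),
                         index=list("abcd"), columns=list("xyz"))
    with pytest.raises(DegenerateTableError):
        bg.gge_analysis(table)


def test_planted_stable_winner_ranks_first():
    """12 genotypes x 5 environments with one genotype having the largest
    main effect and zero interaction: it must rank 1, matching a
    brute-force distance computation."""
    rng = np.random.default_rng(4)
    n_g, n_e = 12, 5
    main = np.sort(rng.normal(0, 300, n_g))[::-1]
    main[0] = main[1] + 500  # clear winner
    inter = rng.normal(0, 150, (n_g, n_e))
    inter[0, :] = 0.0        # perfectly stable
    env = rng.normal(0, 200, n_e)
    table = pd.DataFrame(3000 + main[:, None] + env[None, :] + inter,
                         index=[f"g{i:02d}" for i in range(n_g)],
                         columns=[f"e{j}" for j in range(n_e)])
    res = bg.gge_analysis(table)
    top = res.stability_rank.iloc[0]
    assert top["genotype"] == "g00"
    # brute-force distance oracle in the PC1-PC2 plane
    d = np.linalg.norm(res.genotype_scores[:, :2] - res.ideal_point, axis=1)
    order = np.argsort(d)
    assert res.genotypes[order[0]] == "g00"
    ranked = res.stability_rank.set_index("genotype")["stability_rank"]
    assert ranked["g00"] == 1


def test_sign_flip_invariance_of_ranks():
    rng = np.random.default_rng(5)
    table = pd.DataFrame(rng.normal(3000, 300, (10, 4)),
                         index=[f"g{i}" for i in range(10)],
                         columns=list("wxyz"))
    res = bg.gge_analysis(table)
    flipped = bg.gge_analysis(table)
    flipped.genotype_scores[:, 0] *= -1
    flipped.environment_scores[:, 0] *= -1
    axis = flipped.environment_scores[:, :2].mean(axis=0)
    axis /= np.linalg.norm(axis)
    proj = flipped.genotype_scores[:, :2] @ axis
    ideal = axis * proj.max()
    d = np.linalg.norm(flipped.genotype_scores[:, :2] - ideal, axis=1)
    rank = np.argsort(np.argsort(d)) + 1
    orig = res.stability_rank.set_index("genotype")["stability_rank"]
    assert list(rank) == [orig[g] for g in flipped.genotypes]
    assert np.allclose(res.pc_variance_pct, flipped.pc_variance_pct)


def test_environment_constant_shift_leaves_scores_unchanged():
    rng = np.random.default_rng(6)
    table = pd.DataFrame(rng.normal(3000, 300, (8, 4)),
                         index=[f"g{i}" for i in range(8)],
                         columns=list("wxyz"))
    res1 = bg.gge_analysis(table)
    shifted = table.copy()
    shifted["x"] = shifted["x"] + 750.0
    res2 = bg.gge_analysis(shifted)
    assert np.allclose(res1.genotype_scores, res2.genotype_scores)


def test_rank_report_merge_hand_built(tmp_path):
    rng = np.random.default_rng(7)
    table = pd.DataFrame(rng.normal(3000, 200, (5, 3)),
                         index=[f"g{i}" for i in range(5)],
                         columns=list("abc"))
    gge = bg.gge_analysis(table)
    s2 = pd.DataFrame({"genotype": [f"g{i}" for i in range(5)],
                       "breeding_value": [3100.0, 2900, 3300, 2500, 3050],
                       "reliability": [0.8, 0.5, 0.9, 0.3, 0.6]})
    panel = bg.select_elite(s2, bv_threshold=3000.0, rel_threshold=0.4)
    report = bg.rank_report(gge, panel, stage2_table=s2,
                            path=tmp_path / "report")
    assert len(report) == 5
    by_g = report.set_index("genotype")
    assert bool(by_g.loc["g2", "in_panel"]) is True
    assert bool(by_g.loc["g3", "in_panel"]) is False  # low reliability + BV
    assert by_g.loc["g0", "breeding_value"] == 3100.0
    assert (tmp_path / "report.csv").exists()
    assert (tmp_path / "report.json").exists()


def test_empty_panel_report_headers_only(tmp_path):
    rng = np.random.default_rng(8)
    table = pd.DataFrame(rng.normal(3000, 200, (5, 3)),
                         index=[f"g{i}" for i in range(5)],
                         columns=list("abc"))
    gge = bg.gge_analysis(table)
    s2 = pd.DataFrame({"genotype": [], "breeding_value": [],
                       "reliability": []})
    panel = bg.select_elite(s2, bv_threshold=0.0)
    report = bg.rank_report(gge, panel)
    assert not report["in_panel"].any()
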
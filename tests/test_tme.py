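from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oracles import ssgsea_oracle, wilcoxon_exact_oracle

from exopair.data_io import ExpressionMatrix, GeneSetCollection
from exopair.tme_scoring import (
    ESTIMATE_PURITY_INTERCEPT,
    ESTIMATE_PURITY_SLOPE,
    estimate_scores,
    group_compare,
    load_fixture_gmt,
    ssgsea,
)


def _em(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), "TPM")


class TestSsgsea:
    def test_matches_hand_walked_oracle(self):
        rng = np.random.default_rng(0)
        em = _em(rng.uniform(1, 100, size=(5, 4)))
        sets = GeneSetCollection({"top2": ["g1", "g3"]})
        scores = ssgsea(em, sets, alpha=0.25)
        mask = np.array([g in ("g1", "g3") for g in em.gene_ids])
        for j, s in enumerate(em.sample_ids):
            expected = ssgsea_oracle(em.values.to_numpy()[:, j], mask, 0.25)
            assert scores.loc[s, "top2"] == pytest.approx(expected)

    def test_top_set_beats_bottom_set(self):
        rng = np.random.default_rng(1)
        arr = np.sort(rng.uniform(1, 100, size=(10, 6)), axis=0)[::-1]  # g0 highest
        em = _em(arr)
        sets = GeneSetCollection({"top": ["g0", "g1", "g2"], "bottom": ["g7", "g8", "g9"]})
        scores = ssgsea(em, sets)
        assert (scores["top"] > scores["bottom"]).all()

    def test_exact_rank_invariance(self):
        rng = np.random.default_rng(2)
        arr = rng.uniform(1, 100, size=(8, 5))
        em = _em(arr)
        em2 = _em(np.exp(0.3 * arr) + 7.0)  # strictly increasing transform
        sets = GeneSetCollection({"s": ["g1", "g4", "g6"]})
        assert np.array_equal(ssgsea(em, sets).to_numpy(), ssgsea(em2, sets).to_numpy())

    def test_alpha_zero_depends_only_on_positions(self):
        sets = GeneSetCollection({"s": ["g0", "g2"]})
        a = _em(np.array([[40.0], [30.0], [20.0], [10.0]]))
        b = _em(np.array([[400.0], [31.0], [22.0], [1.0]]))  # same ordering
        sa = ssgsea(a, sets, alpha=0.0)
        sb = ssgsea(b, sets, alpha=0.0)
        assert sa.iloc[0, 0] == pytest.approx(sb.iloc[0, 0])

    def test_absent_set_scores_nan_and_run_continues(self):
        em = _em(np.random.default_rng(3).uniform(size=(4, 2)))
        sets = GeneSetCollection({"absent": ["zz1"], "ok": ["g0"]})
        scores = ssgsea(em, sets)
        assert scores["absent"].isna().all()
        assert scores["ok"].notna().all()

    def test_reversal_flips_top_vs_bottom(self):
        rng = np.random.default_rng(4)
        arr = np.sort(rng.uniform(1, 100, size=(9, 3)), axis=0)[::-1]
        em = _em(arr)
        rev = _em(arr.max() + arr.min() - arr)
        sets = GeneSetCollection({"top": ["g0", "g1"], "bottom": ["g7", "g8"]})
        fwd = ssgsea(em, sets)
        bwd = ssgsea(rev, sets)
        assert (fwd["top"] > fwd["bottom"]).all()
        assert (bwd["top"] < bwd["bottom"]).all()


class TestEstimateScores:
    def test_purity_is_deterministic_cosine_of_combined(self):
        rng = np.random.default_rng(5)
        em = _em(rng.uniform(1, 100, size=(20, 6)))
        out = estimate_scores(em, [f"g{i}" for i in range(5)], [f"g{i}" for i in range(10, 15)])
        recomputed = np.cos(ESTIMATE_PURITY_INTERCEPT + ESTIMATE_PURITY_SLOPE * out["combined"])
        assert np.array_equal(out["purity"].to_numpy(), recomputed.to_numpy())
        assert np.allclose(out["combined"], out["stromal"] + out["immune"])

    def test_zero_combined_reference_value(self):
        # purity at combined score 0 is cos(0.6049872018) ~ 0.8225
        assert np.cos(ESTIMATE_PURITY_INTERCEPT) == pytest.approx(0.82251, abs=5e-5)

    def test_planted_immune_gradient_is_monotone(self):
        # enrichment is rank-based, so the planted gradient must move the
        # immune genes' rank positions: each step crosses two background genes
        background = np.tile(np.arange(10.0, 101.0, 10.0)[:, None], (1, 5))
        immune = np.tile(5.0 + 22.0 * np.arange(5.0)[None, :], (3, 1))
        em = _em(
            np.vstack([background, immune]),
            genes=[f"g{i}" for i in range(10)] + ["i0", "i1", "i2"],
        )
        out = estimate_scores(em, ["g8", "g9"], ["i0", "i1", "i2"])
        assert np.all(np.diff(out["immune"]) > 0)
        by_combined = out.sort_values("combined")["purity"].to_numpy()
        assert np.all(np.diff(by_combined) < 0)

    def test_purity_within_cosine_range(self):
        rng = np.random.default_rng(7)
        em = _em(rng.uniform(1, 1000, size=(30, 8)))
        out = estimate_scores(em, [f"g{i}" for i in range(4)], [f"g{i}" for i in range(20, 26)])
        assert np.all(np.abs(out["purity"]) <= 1.0)


class TestGroupCompare:
    def test_two_group_matches_exact_wilcoxon(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.normal(size=(3, 12)),
                             index=["f1", "f2", "f3"],
                             columns=[f"s{i}" for i in range(12)])
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=table.columns)
        out = group_compare(table, groups)
        for feat in table.index:
            _u, p_o = wilcoxon_exact_oracle(table.loc[feat][:6], table.loc[feat][6:])
            assert out.loc[feat, "pvalue"] == pytest.approx(p_o)

    def test_kw_equals_squared_z_for_two_groups(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=300)
        y = rng.normal(size=300) + 0.2
        h, _ = sps.kruskal(x, y)
        u, pu = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                 use_continuity=False)
        z = sps.norm.isf(pu / 2)
        assert h == pytest.approx(z**2, rel=1e-6)

    def test_three_groups_use_kruskal_and_shift_detected(self):
        rng = np.random.default_rng(10)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 1, 50),
                               rng.normal(2, 1, 50)])
        table = pd.DataFrame(vals[None, :], index=["f"],
                             columns=[f"s{i}" for i in range(150)])
        groups = pd.Series(["a"] * 50 + ["b"] * 50 + ["c"] * 50, index=table.columns)
        out = group_compare(table, groups)
        assert out.loc["f", "pvalue"] < 0.001
        assert out.loc["f", "stars"] == "***"

    def test_constant_feature_gets_p_one(self):
        table = pd.DataFrame(np.ones((1, 10)), index=["flat"],
                             columns=[f"s{i}" for i in range(10)])
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=table.columns)
        out = group_compare(table, groups)
        assert out.loc["flat", "pvalue"] == 1.0

    def test_compositional_table_comparison(self):
        rng = np.random.default_rng(11)
        comp = rng.dirichlet([5, 3, 1, 1, 0.5], size=30).T
        comp[0, 15:] *= 2.0
        comp /= comp.sum(axis=0)
        table = pd.DataFrame(comp, index=[f"phylum{i}" for i in range(5)],
                             columns=[f"s{i}" for i in range(30)])
        groups = pd.Series(["low"] * 15 + ["high"] * 15, index=table.columns)
        out = group_compare(table, groups)
        assert set(out.columns) >= {"statistic", "pvalue", "fdr", "stars"}
        assert out["pvalue"].between(0, 1).all()


def test_fixture_gmt_files_load():
    panel = load_fixture_gmt("checkpoint_panel")
    assert panel["IMMUNE_CHECKPOINT_PANEL"] == ["PDCD1", "CTLA4", "HAVCR2", "LAG3"]
    immune = load_fixture_gmt("immune29_synthetic")
    assert len(immune) == 29
    est = load_fixture_gmt("estimate_synthetic")
    assert set(est.names()) == {"STROMAL_SIGNATURE_SYNTHETIC", "IMMUNE_SIGNATURE_SYNTHETIC"}
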
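"""Signature survival: differential sets, PLAGE, median split, log-rank."""

import numpy as np
import pandas as pd
import pytest

import stagesynergy as ss


def expr_from(values: np.ndarray, stages, genes=None):
    n = values.shape[1]
    samples = [f"s{i}" for i in range(n)]
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return ss.StageLabeledExpression(
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_stage=pd.Series(stages, index=samples),
        gene_class=pd.Series("mRNA", index=genes))


class TestStage4Sets:
    def test_obvious_up_gene(self):
        vals = np.r_[np.ones(30), np.full(10, 10.0)][None, :]
        expr = expr_from(vals, [1] * 30 + [4] * 10)
        up, down = ss.stage4_differential_sets(expr, ["g0"], stage=4)
        assert up == ["g0"] and down == []

    def test_constant_gene_excluded(self):
        expr = expr_from(np.ones((1, 40)), [1] * 30 + [4] * 10)
        up, down = ss.stage4_differential_sets(expr, ["g0"], stage=4)
        assert up == [] and down == []

    def test_empty_universe_errors(self):
        expr = expr_from(np.ones((1, 4)), [1, 1, 4, 4])
        with pytest.raises(ValueError, match="empty"):
            ss.stage4_differential_sets(expr, ["ghost"], stage=4)

    def test_planted_shift_recovered(self):
        """1-SD up-shift in stage 4, n = 50 vs 150: recall >= 0.9."""
        rng = np.random.default_rng(0)
        n_genes = 40
        vals = rng.standard_normal((n_genes, 200))
        vals[:20, 150:] += 1.0  # first 20 genes up-shifted in stage 4
        expr = expr_from(vals, [1] * 150 + [4] * 50)
        up, down = ss.stage4_differential_sets(expr, list(expr.values.index),
                                               stage=4)
        planted = {f"g{i}" for i in range(20)}
        recall = len(planted & set(up)) / 20
        assert recall >= 0.9


class TestPlage:
    def test_singleton_set_is_normalised_zscore(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((3, 30))
        expr = pd.DataFrame(vals, index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(30)])
        score = ss.plage_scores(expr, ["a"])
        z = (vals[0] - vals[0].mean()) / vals[0].std()
        expected = z / np.linalg.norm(z)
        np.testing.assert_allclose(score.to_numpy(), expected, atol=1e-10)

    def test_duplicate_gene_same_direction(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((2, 20))
        vals[1] = vals[0]
        expr = pd.DataFrame(vals, index=["a", "b"],
                            columns=[f"s{i}" for i in range(20)])
        s1 = ss.plage_scores(expr, ["a"])
        s2 = ss.plage_scores(expr, ["a", "b"])
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)

    def test_matches_svd_oracle(self):
        """Random 5 x 30 matrix: scores equal the oracle's first right
        singular vector up to the documented sign orientation."""
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((5, 30))
        expr = pd.DataFrame(vals, index=list("abcde"),
                            columns=[f"s{i}" for i in range(30)])
        score = ss.plage_scores(expr, list("abcde"))
        z = (vals - vals.mean(1, keepdims=True)) / vals.std(1, keepdims=True)
        v = np.linalg.svd(z)[2][0]
        if v @ z.mean(0) < 0:
            v = -v
        np.testing.assert_allclose(score.to_numpy(), v, atol=1e-10)
        assert np.linalg.norm(score) == pytest.approx(1.0)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((4, 25))
        expr = pd.DataFrame(vals, index=list("abcd"),
                            columns=[f"s{i}" for i in range(25)])
        base = ss.plage_scores(expr, list("abcd"))
        scaled = expr * 3.5 + 11.0
        np.testing.assert_allclose(
            ss.plage_scores(scaled, list("abcd")).to_numpy(),
            base.to_numpy(), atol=1e-10)

    def test_zero_variance_gene_dropped(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((2, 20))
        vals[1] = 7.0
        expr = pd.DataFrame(vals, index=["a", "flat"],
                            columns=[f"s{i}" for i in range(20)])
        s = ss.plage_scores(expr, ["a", "flat"])
        np.testing.assert_allclose(s.to_numpy(),
                                   ss.plage_scores(expr, ["a"]).to_numpy(),
                                   atol=1e-12)

    def test_all_missing_errors(self):
        expr = pd.DataFrame(np.ones((1, 5)), index=["a"],
                            columns=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError):
            ss.plage_scores(expr, ["nope"])


class TestMedianSplit:
    def test_even_split(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        g = ss.median_split(s)
        assert list(g) == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        g = ss.median_split(s)
        assert g["c"] == "low"
        assert (g == "high").sum() == 2 and (g == "low").sum() == 3

    def test_all_equal_all_low(self):
        s = pd.Series([2.0] * 4, index=list("abcd"))
        assert (ss.median_split(s) == "low").all()


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        surv = pd.DataFrame({"time": [1, 2, 3, 1, 2, 3],
                             "event": [1, 1, 1, 1, 1, 1]},
                            index=list("abcdef"))
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=list("abcdef"))
        chi2, p = ss.logrank(surv, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        """times 1..4, all events, groups {1,2} vs {3,4}: O-E table by hand.

        Event times 1,2,3,4; group A = samples with times 1,2.
        t=1: at risk A=2,B=2, d=1, E_A=0.5, V=0.25
        t=2: at risk A=1,B=2, d=1, E_A=1/3, V=2/9
        t=3: at risk A=0,B=2, d=1, E_A=0,   V=0
        t=4: at risk A=0,B=1, d=1, E_A=0,   V=0
        O_A=2, E_A=5/6, V=0.25+2/9  ->  chi2 = (2-5/6)^2 / (17/36)
        """
        surv = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 1, 1]},
                            index=list("abcd"))
        groups = pd.Series(["A", "A", "B", "B"], index=list("abcd"))
        chi2, p = ss.logrank(surv, groups)
        expected = (2 - 5 / 6) ** 2 / (0.25 + 2 / 9)
        assert chi2 == pytest.approx(expected, abs=1e-10)

    def test_group_label_symmetric(self):
        rng = np.random.default_rng(6)
        surv = pd.DataFrame({"time": rng.exponential(10, 40),
                             "event": rng.integers(0, 2, 40)},
                            index=[f"s{i}" for i in range(40)])
        g = pd.Series(["x"] * 20 + ["y"] * 20, index=surv.index)
        chi2a, pa = ss.logrank(surv, g)
        chi2b, pb = ss.logrank(surv, g.map({"x": "y", "y": "x"}))
        assert chi2a == pytest.approx(chi2b)
        assert pa == pytest.approx(pb)

    def test_zero_events_errors(self):
        surv = pd.DataFrame({"time": [5.0, 5.0], "event": [0, 0]}, index=["a", "b"])
        groups = pd.Series(["high", "low"], index=["a", "b"])
        with pytest.raises(ValueError):
            ss.logrank(surv, groups)

    def test_one_group_errors(self):
        surv = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]}, index=["a", "b"])
        groups = pd.Series(["low", "low"], index=["a", "b"])
        with pytest.raises(ValueError):
            ss.logrank(surv, groups)

    def test_early_censored_do_not_change_statistic(self):
        """Censored observations before the first event leave chi2 unchanged."""
        surv = pd.DataFrame({"time": [5, 6, 7, 8], "event": [1, 1, 1, 1]},
                            index=list("abcd"))
        groups = pd.Series(["A", "B", "A", "B"], index=list("abcd"))
        chi2_base, _ = ss.logrank(surv, groups)
        surv2 = pd.concat([surv, pd.DataFrame(
            {"time": [1, 1], "event": [0, 0]}, index=["x", "y"])])
        groups2 = pd.concat([groups, pd.Series(["A", "B"], index=["x", "y"])])
        chi2_more, _ = ss.logrank(surv2, groups2)
        assert chi2_more == pytest.approx(chi2_base, abs=1e-10)


class TestSignatureSurvival:
    def test_end_to_end_with_planted_effect(self):
        cfg = ss.SimulationConfig(samples_per_stage=(150,), n_stages=1,
                                  n_lncrna=10, n_mrna=30, n_icp=3,
                                  n_planted_specific=2, n_planted_uniform=0,
                                  n_null_pairs=0, n_decoy_pairs=0, seed=21)
        cfg.survival.effect_size = 1.5
        expr, _ = ss.simulate_expression(cfg)
        genes = list(expr.values.index[:5])
        scores = ss.plage_scores(expr.values, genes)
        z = (scores - scores.mean()) / scores.std(ddof=0)
        surv = ss.simulate_survival(cfg, z)
        out = ss.signature_survival(expr, surv, genes)
        assert out["logrank_p"] < 0.01
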
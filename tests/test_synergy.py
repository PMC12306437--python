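"""Synergy scoring: adjusted PCC, the score's closed forms, permutation p."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stagesynergy as ss
from stagesynergy.synergy import (StageCorrelationProfile, _pearson_rows,
                                  _ssliss_rows)


def ssliss_oracle(adjusted):
    """Independent direct transcription of the printed score formula."""
    adj = np.abs(np.asarray(adjusted, float))
    max_abs = adj.max()
    if max_abs == 0:
        return 0.0
    total = sum(1 - a / max_abs for a in adj)
    return total / (len(adj) - 1) * (max_abs / 0.75)


def profile_from(adjusted):
    adj = np.asarray(adjusted, float)
    return StageCorrelationProfile(
        pair_id="p", stages=np.arange(1, len(adj) + 1),
        r=adj.copy(), p=np.where(adj != 0, 0.01, 0.5),
        adjusted_r=adj, n=np.full(len(adj), 50))


class TestPearson:
    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 30))
        r, p = _pearson_rows(x, y)
        sr, sp = stats.pearsonr(x, y)
        assert r[0] == pytest.approx(sr, abs=1e-12)
        assert p[0] == pytest.approx(sp, rel=1e-9)

    def test_textbook_formula_oracle(self):
        """Brute-force covariance/sigma computation on a printed fixture."""
        x = np.array([1.0, 2.0, 4.0, 4.5, 6.0, 7.0, 8.5, 10.0])
        y = np.array([2.1, 1.9, 4.2, 5.0, 5.5, 8.1, 7.9, 9.6])
        r, _ = _pearson_rows(x, y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        oracle = cov / (x.std() * y.std())
        assert r[0] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_row(self):
        r, p = _pearson_rows(np.ones(10), np.arange(10.0))
        assert r[0] == 0.0 and p[0] == 1.0


class TestStageCorrelations:
    def test_perfect_linearity(self, tiny_expr):
        tiny_expr.values.loc["M1"] = 2 * tiny_expr.values.loc["L1"] + 1
        prof = ss.stage_correlations(tiny_expr, "L1", "M1")
        assert prof.r == pytest.approx([1.0, 1.0])
        assert prof.adjusted_r == pytest.approx([1.0, 1.0])

    def test_nonsignificant_r_zeroed(self):
        """Adjusted PCC is 0 whenever the correlation p is >= 0.05."""
        rng = np.random.default_rng(5)
        # weak correlation at small n: p > 0.05, so adjusted must be 0
        n = 12
        samples = [f"s{i}" for i in range(2 * n)]
        x = rng.standard_normal(2 * n)
        y = 0.3 * x + rng.standard_normal(2 * n)
        expr = ss.StageLabeledExpression(
            values=pd.DataFrame([x, y], index=["L1", "M1"], columns=samples),
            sample_stage=pd.Series([1] * n + [2] * n, index=samples),
            gene_class=pd.Series(["lncRNA", "mRNA"], index=["L1", "M1"]))
        prof = ss.stage_correlations(expr, "L1", "M1")
        for rj, pj, aj in zip(prof.r, prof.p, prof.adjusted_r):
            assert aj == (rj if pj < 0.05 else 0.0)

    def test_min_samples_enforced(self, tiny_expr):
        small = tiny_expr.subset_samples(list(tiny_expr.values.columns[:12]))
        small.sample_stage.iloc[:] = [1] * 10 + [2] * 2
        with pytest.raises(ValueError, match=">= 3"):
            ss.stage_correlations(small, "L1", "M1")


class TestSsliss:
    def test_uniform_profile_scores_zero(self):
        assert ss.ssliss(np.array([0.6, 0.6, 0.6])) == 0.0

    def test_single_stage_at_0p75_scores_one(self):
        assert ss.ssliss(np.array([0.75, 0, 0, 0])) == pytest.approx(1.0)

    def test_worked_example(self):
        # terms (0, 0.6, 1), sum 1.6, /2 = 0.8, x 0.75/0.75
        assert ss.ssliss(np.array([0.75, 0.3, 0.0])) == pytest.approx(0.8)

    def test_all_zero_profile_scores_zero(self):
        assert ss.ssliss(np.zeros(3)) == 0.0

    def test_matches_independent_oracle_on_random_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            adj = rng.uniform(-1, 1, rng.integers(2, 6))
            adj[rng.random(adj.size) < 0.4] = 0.0
            assert ss.ssliss(adj) == pytest.approx(ssliss_oracle(adj), abs=1e-12)

    def test_vectorised_rows_match_scalar(self):
        rng = np.random.default_rng(1)
        adj = rng.uniform(-1, 1, (200, 4))
        adj[rng.random(adj.shape) < 0.5] = 0.0
        rows = _ssliss_rows(adj)
        for i in range(200):
            assert rows[i] == pytest.approx(ss.ssliss(adj[i]), abs=1e-12)

    def test_range_bound(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            adj = rng.uniform(-1, 1, rng.integers(2, 6))
            assert 0 <= ss.ssliss(adj) <= 1 / 0.75 + 1e-12

    def test_single_significant_stage_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(2, 6)
            adj = np.zeros(n)
            adj[rng.integers(n)] = rng.uniform(-1, 1)
            expect = abs(adj).max() / 0.75
            if abs(adj).max() > 0:
                assert ss.ssliss(adj) == pytest.approx(expect, abs=1e-12)

    def test_fewer_than_two_stages_errors(self):
        with pytest.raises(ValueError):
            ss.ssliss(np.array([0.5]))


class TestSpecificStage:
    def test_argmax_of_absolute_values(self):
        prof = profile_from([0.2, -0.9, 0.4])
        assert ss.assign_specific_stage(prof) == 2

    def test_tie_broken_by_earliest_stage(self):
        assert ss.assign_specific_stage(profile_from([0.8, 0.8])) == 1

    def test_no_significant_stage_returns_none(self):
        assert ss.assign_specific_stage(profile_from([0.0, 0.0])) is None


class TestPermutation:
    def build_expr(self, r_by_stage, n=40, seed=0):
        rng = np.random.default_rng(seed)
        xs, ys, labels = [], [], []
        for s, r in enumerate(r_by_stage, start=1):
            x = rng.standard_normal(n)
            y = r * x + np.sqrt(1 - r**2) * rng.standard_normal(n)
            xs.append(x); ys.append(y); labels += [s] * n
        samples = [f"s{i}" for i in range(len(labels))]
        return ss.StageLabeledExpression(
            values=pd.DataFrame([np.concatenate(xs), np.concatenate(ys)],
                                index=["L1", "M1"], columns=samples),
            sample_stage=pd.Series(labels, index=samples),
            gene_class=pd.Series(["lncRNA", "mRNA"], index=["L1", "M1"]))

    def test_strong_specific_pair_gets_minimal_p(self):
        expr = self.build_expr([0.9, 0.0, 0.0], n=60, seed=1)
        p, null = ss.permutation_pvalue(expr, "L1", "M1", B=200, seed=0)
        assert p == pytest.approx(1 / 201)
        assert len(null) == 200

    def test_addone_bounds(self):
        expr = self.build_expr([0.3, 0.3], n=30, seed=2)
        p, _ = ss.permutation_pvalue(expr, "L1", "M1", B=7, seed=0)
        assert 1 / 8 <= p <= 1.0

    def test_observed_zero_never_beats_null(self):
        expr = self.build_expr([0.0, 0.0], n=10, seed=3)
        prof = ss.stage_correlations(expr, "L1", "M1")
        if ss.ssliss(prof) == 0.0:
            p, _ = ss.permutation_pvalue(expr, "L1", "M1", B=50, seed=0)
            assert p == 1.0

    def test_deterministic_given_seed(self):
        expr = self.build_expr([0.7, 0.0], n=30, seed=4)
        p1, n1 = ss.permutation_pvalue(expr, "L1", "M1", B=100, seed=9)
        p2, n2 = ss.permutation_pvalue(expr, "L1", "M1", B=100, seed=9)
        assert p1 == p2
        np.testing.assert_array_equal(n1, n2)


class TestScoreAll:
    def test_empty_candidates(self, small_expr):
        out = ss.score_all(small_expr, pd.DataFrame(columns=["lncrna", "mrna"]),
                           B=10)
        assert out.empty

    def test_order_independent(self, small_sim):
        expr = ss.filter_stages(small_sim["expression"], 10)
        cand = ss.build_candidates(expr, small_sim["ppi"], small_sim["catalog"],
                                   small_sim["icps"]).head(6)
        a = ss.score_all(expr, cand, B=50, seed=5)
        b = ss.score_all(expr, cand.iloc[::-1], B=50, seed=5)
        b = b.sort_values("pair_id").reset_index(drop=True)
        a = a.sort_values("pair_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_scale_invariance(self, small_sim):
        """Multiplying a gene's expression by a positive constant changes nothing."""
        expr = ss.filter_stages(small_sim["expression"], 10)
        cand = ss.build_candidates(expr, small_sim["ppi"], small_sim["catalog"],
                                   small_sim["icps"]).head(3)
        base = ss.score_all(expr, cand, B=50, seed=5)
        scaled = expr.values.copy()
        for g in cand["lncrna"]:
            scaled.loc[g] *= 7.3
        expr2 = ss.StageLabeledExpression(values=scaled,
                                          sample_stage=expr.sample_stage,
                                          gene_class=expr.gene_class,
                                          icp_flag=expr.icp_flag)
        again = ss.score_all(expr2, cand, B=50, seed=5)
        pd.testing.assert_frame_equal(base, again, atol=1e-9, rtol=0)
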
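"""Rank statistics, multiplicity control and the screening workflows."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rnastab.screening import (anova_oneway, bonferroni_adjust, build_network,
                               ks_two_sample, screen_features, spearman_test,
                               stratify_by_exon, subsample_stability)
from rnastab.seqfeatures import TranscriptRecord


def spearman_permutation_oracle(x, y):
    """Exact permutation p by independent enumeration via scipy rankdata."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)

    def rho(a, b):
        return np.corrcoef(a, b)[0, 1]

    obs = abs(rho(rx, ry))
    hits = total = 0
    for perm in permutations(ry):
        total += 1
        if abs(rho(rx, np.array(perm))) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestSpearman:
    def test_monotone_perfect(self):
        rho, _ = spearman_test([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_test([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(size=7)
            y = 0.5 * x + rng.normal(size=7)
            rho, p = spearman_test(x, y)
            oracle = spearman_permutation_oracle(x, y)
            assert p == pytest.approx(oracle, rel=1e-9)

    def test_tied_data_matches_rank_pearson(self):
        x = [1, 2, 2, 3, 4, 4, 5, 6, 7, 8, 9]
        y = [2, 1, 3, 3, 5, 4, 6, 6, 8, 7, 9]
        rho, _ = spearman_test(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle)

    def test_large_n_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        y = 0.3 * x + rng.normal(size=60)
        rho, p = spearman_test(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            spearman_test([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            spearman_test([1, 2, 3], [3, 2, 1])


class TestKS:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == pytest.approx(1.0)

    def test_matches_ecdf_scan_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=rng.integers(5, 30))
            y = rng.normal(0.5, 1.2, size=rng.integers(5, 30))
            d, _ = ks_two_sample(x, y)
            grid = np.concatenate([x, y])
            ecdf_x = np.array([(x <= g).mean() for g in grid])
            ecdf_y = np.array([(y <= g).mean() for g in grid])
            assert d == pytest.approx(np.abs(ecdf_x - ecdf_y).max())

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestAnova:
    def test_identical_groups(self):
        g = np.linspace(0, 1, 20)
        f, p = anova_oneway([g, g, g])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_textbook_closed_form(self):
        groups = [[1.0, 2, 3], [2.0, 3, 4], [4.0, 5, 6]]
        k, n = 3, 9
        grand = np.mean(np.concatenate(groups))
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum()
                        for g in groups)
        f_expected = (ss_between / (k - 1)) / (ss_within / (n - k))
        f, p = anova_oneway(groups)
        assert f == pytest.approx(f_expected)
        assert p == pytest.approx(stats.f.sf(f_expected, k - 1, n - k))

    def test_shifting_a_group_increases_f(self):
        rng = np.random.default_rng(9)
        base = [rng.normal(size=20) for _ in range(3)]
        f_prev = None
        for shift in (0.0, 0.5, 1.0, 2.0):
            groups = [base[0] + shift, base[1], base[2]]
            f, _ = anova_oneway(groups)
            if f_prev is not None:
                assert f > f_prev
            f_prev = f

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 2.0]])
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0]])


class TestBonferroni:
    def test_examples(self):
        assert bonferroni_adjust([0.001], m=10)[0] == pytest.approx(0.01)
        assert bonferroni_adjust([0.5], m=10)[0] == 1.0
        assert bonferroni_adjust([0.3])[0] == pytest.approx(0.3)  # m = 1

    def test_monotone_and_idempotent_after_cap(self):
        ps = np.array([0.0001, 0.01, 0.2, 0.9])
        adj = bonferroni_adjust(ps)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(bonferroni_adjust(adj, m=1) == adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])
        with pytest.raises(ValueError):
            bonferroni_adjust([-0.1])


class TestStratify:
    def test_partition(self):
        recs = [TranscriptRecord(f"t{i}", "ACGU" * 10, exon_count=c)
                for i, c in enumerate([1, 1, 2, 5])]
        strata = stratify_by_exon(recs)
        assert len(strata["lnc1"]) == 2 and len(strata["lnc2"]) == 2
        assert not strata["m1"] and not strata["m2"]
        total = sum(len(v) for v in strata.values())
        assert total == len(recs)

    def test_all_single_exon(self):
        recs = [TranscriptRecord(f"t{i}", "ACGU" * 10) for i in range(3)]
        strata = stratify_by_exon(recs)
        assert len(strata["lnc1"]) == 3 and not strata["lnc2"]


class TestScreenFeatures:
    def _data(self, n=400, n_feat=20, n_effect=5, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, n_feat))
        y = np.exp(0.5 * rng.normal(size=n)
                   + X[:, :n_effect] @ np.full(n_effect, 0.6))
        feats = pd.DataFrame(X, index=[f"t{i}" for i in range(n)],
                             columns=[f"f{j}" for j in range(n_feat)])
        hl = pd.Series(y, index=feats.index, name="t_half_mean")
        return hl, feats

    def test_planted_effects_recovered_with_sign(self):
        hl, feats = self._data()
        hits, summary = screen_features(hl, feats)
        sig = {h.feature_name: h for h in hits if h.fdr < 0.01}
        for j in range(5):
            assert f"f{j}" in sig
            assert sig[f"f{j}"].direction == "positive"
        assert summary == "5/5"

    def test_null_features_stay_silent(self):
        rng = np.random.default_rng(11)
        hl = pd.Series(np.exp(rng.normal(size=300)),
                       index=[f"t{i}" for i in range(300)])
        feats = pd.DataFrame(rng.normal(size=(300, 50)), index=hl.index)
        feats.columns = [f"f{j}" for j in feats.columns]
        hits, summary = screen_features(hl, feats)
        assert summary.endswith("/0")

    def test_feature_identical_to_halflife(self):
        hl, feats = self._data(n=100, n_feat=1, n_effect=0)
        feats["f0"] = hl.values
        hits, summary = screen_features(hl, feats)
        assert hits[0].rho == pytest.approx(1.0)
        assert summary == "1/1"

    def test_zero_variance_feature_skipped(self):
        hl, feats = self._data(n=50, n_feat=3, n_effect=0)
        feats["f0"] = 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            hits, _ = screen_features(hl, feats)
        assert all(h.feature_name != "f0" for h in hits)

    def test_ks_binary_mode(self):
        rng = np.random.default_rng(13)
        n = 300
        carrier = rng.random(n) < 0.5
        y = np.exp(rng.normal(size=n) + 1.0 * carrier)
        hl = pd.Series(y, index=[f"t{i}" for i in range(n)])
        feats = pd.DataFrame({"site": carrier.astype(float)}, index=hl.index)
        hits, _ = screen_features(hl, feats, method="ks_binary")
        assert hits[0].fdr < 0.01 and hits[0].direction == "positive"


class TestSubsample:
    def test_counts_decrease_with_n_on_planted_effect(self):
        # weak planted correlation (rho ~ 0.08): detectable only with many
        # transcripts, so the miss count falls steeply over the n grid
        rng = np.random.default_rng(17)
        n = 12000
        x = rng.normal(size=n)
        y = 0.081 * x + rng.normal(size=n)
        table = subsample_stability(y, x, [400, 1500, 3000], reps=100, seed=5)
        counts = table.n_p_above_alpha.to_numpy()
        assert counts[0] > counts[1] > counts[2]

    def test_null_calibration(self):
        rng = np.random.default_rng(19)
        y = rng.normal(size=2000)
        x = rng.normal(size=2000)
        table = subsample_stability(y, x, [500], reps=200, alpha=0.1, seed=7)
        frac = table.n_p_above_alpha.iloc[0] / 200
        assert 0.8 < frac <= 1.0  # ~ 1 - alpha

    def test_full_population_is_deterministic(self):
        rng = np.random.default_rng(23)
        y = rng.normal(size=50)
        x = 0.9 * y + 0.1 * rng.normal(size=50)
        table = subsample_stability(y, x, [50], reps=30, seed=1)
        assert table.n_p_above_alpha.iloc[0] in (0, 30)

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError):
            subsample_stability(np.ones(10), np.ones(10), [11], reps=2)


class TestNetwork:
    def test_identical_columns_strong_positive_edge(self):
        rng = np.random.default_rng(29)
        col = rng.normal(size=300)
        table = pd.DataFrame({"a": col, "b": col,
                              "c": rng.normal(size=300)})
        net = build_network(table)
        edges = {(e["source"], e["target"]): e for e in net["edges"]}
        assert ("a", "b") in edges
        e = edges[("a", "b")]
        assert e["sign"] == "+" and e["strength"] == "strong"

    def test_independent_columns_no_edges(self):
        rng = np.random.default_rng(31)
        table = pd.DataFrame(rng.normal(size=(200, 4)),
                             columns=list("abcd"))
        net = build_network(table)
        assert net["edges"] == []

    def test_planted_negative_length_mfe_edge(self):
        rng = np.random.default_rng(37)
        length = np.exp(rng.normal(7, 0.5, 500))
        mfe = -0.3 * length * np.exp(rng.normal(0, 0.05, 500))
        table = pd.DataFrame({"length": length, "mfe": mfe,
                              "noise": rng.normal(size=500)})
        net = build_network(table)
        edges = {(e["source"], e["target"]): e for e in net["edges"]}
        assert ("length", "mfe") in edges
        assert edges[("length", "mfe")]["sign"] == "-"

    def test_all_missing_factor_excluded(self):
        rng = np.random.default_rng(41)
        col = rng.normal(size=100)
        table = pd.DataFrame({"a": col, "b": col + rng.normal(size=100),
                              "empty": np.nan})
        with pytest.warns(UserWarning, match="all-missing"):
            net = build_network(table)
        assert "empty" not in net["nodes"]
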
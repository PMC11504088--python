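"""Differential expression, DEG classification, cross-KD overlap, and trend curve."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from regulomics.kd_integration import (
    classify_degs,
    de_test,
    deregulogram,
    log_cpm,
    overlap_degs,
    score_fc_trend,
)


def _detable(log2fc, p_adj, p=None, biotype="protein_coding"):
    n = len(log2fc)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p if p is not None else p_adj,
            "p_adj": p_adj,
            "mean_expr": np.ones(n),
            "biotype": [biotype] * n,
        },
        index=[f"g{i}" for i in range(n)],
    )


class TestLogCpm:
    def test_hand_computed_3x2(self):
        counts = pd.DataFrame({"s1": [0, 10, 90], "s2": [50, 25, 25]}, index=list("abc"))
        out = log_cpm(counts)
        assert out.loc["a", "s1"] == 0.0  # log2(0 + 1)
        assert out.loc["b", "s1"] == pytest.approx(np.log2(1e6 * 10 / 100 + 1))
        assert out.loc["c", "s2"] == pytest.approx(np.log2(1e6 * 25 / 100 + 1))

    def test_library_scale_invariance(self):
        counts = pd.DataFrame({"s1": [3, 7, 11]}, index=list("abc"))
        doubled = counts * 2
        assert np.allclose(log_cpm(counts), log_cpm(doubled))

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=list("ab"))
        with pytest.raises(ValueError, match="zero library"):
            log_cpm(counts)


class TestDeTest:
    def _groups(self, n):
        g = {f"c{i}": "control" for i in range(n)}
        g.update({f"k{i}": "kd" for i in range(n)})
        return g

    def test_identical_groups_are_null(self):
        data = pd.DataFrame(
            {"c0": [1.0, 2], "c1": [2.0, 3], "k0": [1.0, 2], "k1": [2.0, 3]},
            index=["g1", "g2"],
        )
        out = de_test(data, self._groups(2))
        assert np.allclose(out["log2fc"], 0)
        # constant-difference rows with zero fc get p = 1 when degenerate
        assert (out["p"] > 0.9).all()

    def test_bh_step_up_hand_example(self):
        # p {0.01, 0.02, 0.03, 0.04}, m = 4 -> all adjusted to 0.04
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    def test_p_adj_dominates_p_and_is_monotone(self, rng):
        data = pd.DataFrame(
            rng.normal(5, 1, (300, 8)),
            columns=list(self._groups(4)),
            index=[f"g{i}" for i in range(300)],
        )
        out = de_test(data, self._groups(4))
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        ordered = out.sort_values("p")
        assert (np.diff(ordered["p_adj"]) >= -1e-12).all()
        assert ((out["p"] > 0) & (out["p"] <= 1)).all()

    def test_planted_shift_recovered_with_adequate_replication(self):
        # 16 vs 16 samples, +1 log2 shift, NB dispersion 0.1: BH keeps >=90%
        rng = np.random.default_rng(103)
        n_genes, n_planted, n = 500, 50, 16
        mu = rng.lognormal(5, 0.7, n_genes)
        r = 1 / 0.1
        eff = np.ones(n_genes)
        eff[:n_planted] = 2.0
        cols = {f"c{i}": "control" for i in range(n)}
        cols.update({f"k{i}": "kd" for i in range(n)})
        counts = {}
        for i in range(n):
            counts[f"c{i}"] = rng.negative_binomial(r, r / (r + mu))
            counts[f"k{i}"] = rng.negative_binomial(r, r / (r + mu * eff))
        frame = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)])
        out = de_test(log_cpm(frame), cols)
        assert (out["p_adj"].iloc[:n_planted] <= 0.05).mean() >= 0.9
        assert out["log2fc"].iloc[:n_planted].mean() == pytest.approx(1.0, abs=0.15)

    def test_raw_detection_at_minimal_replication(self, default_sim):
        # at the default 4-vs-4 design most planted genes reach raw p <= 0.05
        sim = default_sim
        cm = sim.counts["gata4"]
        out = de_test(log_cpm(cm), cm.sample_groups)
        planted = list(sim.truth["planted_targets"])
        assert (out.loc[planted, "p"] <= 0.05).mean() >= 0.4
        null = out.drop(index=planted)
        assert 0.02 <= (null["p"] <= 0.05).mean() <= 0.08

    def test_too_few_samples_rejected(self):
        data = pd.DataFrame({"c0": [1.0], "k0": [2.0], "k1": [3.0]}, index=["g"])
        with pytest.raises(ValueError, match="2 samples"):
            de_test(data, {"c0": "control", "k0": "kd", "k1": "kd"})


class TestClassifyDegs:
    def test_thresholds(self):
        table = _detable([0.5, 0.30, np.log2(1.25), -0.5], [0.01, 0.001, 0.04, 0.01])
        out = classify_degs(table)
        assert out.tolist() == ["up", "ns", "up", "down"]  # boundary fc inclusive

    def test_log_scale_option(self):
        table = _detable([1.0, 1.3], [0.01, 0.01])
        out = classify_degs(table, fc_on_log_scale=True, min_linear_fc=1.25)
        assert out.tolist() == ["ns", "up"]

    def test_partition_is_complete_and_order_invariant(self, rng):
        table = _detable(rng.normal(0, 1, 100), rng.uniform(0, 1, 100))
        out = classify_degs(table)
        assert out.value_counts().sum() == 100
        shuffled = classify_degs(table.sample(frac=1, random_state=0))
        assert shuffled.sort_index().equals(out.sort_index())


class TestOverlap:
    def test_disjoint_and_identical(self):
        a = pd.Series(["up", "down", "ns"], index=["g0", "g1", "g2"])
        b = pd.Series(["ns", "ns", "ns"], index=["g0", "g1", "g2"])
        biotypes = pd.Series(["protein_coding"] * 3, index=["g0", "g1", "g2"])
        assert overlap_degs(a, b, biotypes)["common_count"].sum() == 0
        same = overlap_degs(a, a, biotypes)
        assert same["common_count"].sum() == 2  # one up + one down, both coding

    def test_planted_concordant_set_counted_exactly(self):
        k = 7
        genes = [f"g{i}" for i in range(20)]
        cls = pd.Series("ns", index=genes)
        cls.iloc[:k] = "up"
        biotypes = pd.Series(
            ["protein_coding"] * 10 + ["lincRNA"] * 10, index=genes
        )
        out = overlap_degs(cls, cls, biotypes)
        assert out.loc[(out.direction == "up"), "common_count"].sum() == k


class TestDeregulogram:
    def test_identical_tables(self, rng):
        t = _detable(rng.normal(0, 1, 50), np.full(50, 0.01))
        records, summary = deregulogram(t, t)
        assert summary["pearson_r"] == pytest.approx(1.0)
        assert summary["pct_concordant"] == pytest.approx(100.0)
        assert (records["sig_class"] == "both").all()

    def test_antisymmetric_tables(self, rng):
        t = _detable(rng.normal(0, 1, 50), np.full(50, 0.01))
        flipped = t.copy()
        flipped["log2fc"] = -t["log2fc"]
        _records, summary = deregulogram(t, flipped)
        assert summary["pearson_r"] == pytest.approx(-1.0)
        assert summary["pct_concordant"] == pytest.approx(0.0)

    def test_partial_concordance_recovered(self, rng):
        n = 500
        fc1 = rng.normal(0, 1, n)
        flip = rng.random(n) < 0.2  # 80% concordant plants
        fc2 = np.abs(rng.normal(1, 0.2, n)) * np.sign(fc1) * np.where(flip, -1, 1)
        a = _detable(fc1, np.full(n, 0.01))
        b = _detable(fc2, np.full(n, 0.01))
        _records, summary = deregulogram(a, b)
        assert summary["pct_concordant"] == pytest.approx(80.0, abs=5.0)

    def test_sparse_overlap_reports_missing_r(self, caplog):
        a = _detable([1.0, 2.0, 3.0], [0.01, 0.5, 0.5])
        with caplog.at_level("WARNING"):
            _records, summary = deregulogram(a, a)
        assert np.isnan(summary["pearson_r"])


class TestTrend:
    def test_constant_fc_gives_constant_curve(self):
        scores = pd.Series(np.arange(30, dtype=float), index=[f"g{i}" for i in range(30)])
        fcs = pd.Series(0.7, index=scores.index)
        out = score_fc_trend(scores, fcs, window_genes=5)
        assert np.allclose(out["trend"], 0.7)
        assert len(out) == 30

    def test_window_one_is_identity(self, rng):
        idx = [f"g{i}" for i in range(20)]
        scores = pd.Series(rng.uniform(0, 10, 20), index=idx)
        fcs = pd.Series(rng.normal(0, 1, 20), index=idx)
        out = score_fc_trend(scores, fcs, window_genes=1)
        assert np.allclose(out["trend"], out["log2fc"])
        assert out["score"].is_monotonic_increasing

    def test_planted_top_decile_signal(self, rng):
        n = 1000
        idx = [f"g{i}" for i in range(n)]
        scores = pd.Series(np.sort(rng.uniform(0, 100, n)), index=idx)
        fcs = pd.Series(rng.normal(0, 0.3, n), index=idx)
        fcs.iloc[-100:] += 1.0  # positive fc planted on the top score decile
        out = score_fc_trend(scores, fcs, window_genes=100)
        top = out["trend"].iloc[-100:].mean()
        bottom = out["trend"].iloc[:100].mean()
        assert top > bottom + 0.5
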
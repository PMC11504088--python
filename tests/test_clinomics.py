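"""Cohort normalization, metagene scores, ROC, survival, strata, multi-cohort."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from regulomics.clinomics import (
    cross_normalize,
    km_logrank,
    metagene_score,
    multicancer_panel,
    roc_auc,
    roc_by_stage,
    strata_compare,
)


def _cohort(rng, n_genes=50, n_tumor=30, n_normal=20, shift_genes=(), shift=0.0):
    base = rng.normal(5, 1, n_genes)
    idx = [f"g{i}" for i in range(n_genes)]
    tl = base[:, None] + rng.normal(0, 1, (n_genes, n_tumor))
    nl = base[:, None] + rng.normal(0, 1, (n_genes, n_normal))
    for g in shift_genes:
        tl[idx.index(g)] += shift
    tumor = pd.DataFrame(2.0 ** tl, index=idx, columns=[f"t{i}" for i in range(n_tumor)])
    normal = pd.DataFrame(2.0 ** nl, index=idx, columns=[f"n{i}" for i in range(n_normal)])
    return tumor, normal


class TestCrossNormalize:
    def test_row_standardization(self, rng):
        z = cross_normalize(*_cohort(rng))
        assert np.allclose(z.data.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.data.std(axis=1, ddof=0), 1, atol=1e-9)

    def test_sample_scale_invariance(self, rng):
        tumor, normal = _cohort(rng)
        z1 = cross_normalize(tumor, normal)
        tumor2 = tumor.copy()
        tumor2["t0"] = tumor2["t0"] * 10  # upper-quartile scaling absorbs this
        z2 = cross_normalize(tumor2, normal)
        assert np.allclose(z1.data["t0"], z2.data["t0"], atol=1e-9)

    def test_hand_computed_four_samples(self):
        tumor = pd.DataFrame({"t1": [1.0, 2, 3, 4], "t2": [2.0, 4, 6, 8]},
                             index=list("abcd"))
        normal = pd.DataFrame({"n1": [4.0, 3, 2, 1], "n2": [1.0, 3, 2, 4]},
                              index=list("abcd"))
        z = cross_normalize(tumor, normal)
        # step-by-step: UQ of each sample over positive values, scale to mean
        # UQ, log2(x+1), per-gene z with population sd
        uq = pd.concat([tumor, normal], axis=1)[lambda d: d > 0].quantile(0.75)
        scaled = pd.concat([tumor, normal], axis=1) * (1000.0 / uq)
        logged = np.log2(scaled + 1)
        expect = logged.sub(logged.mean(axis=1), axis=0).div(
            logged.std(axis=1, ddof=0), axis=0
        )
        assert np.allclose(z.data, expect)

    def test_zero_variance_genes_dropped(self, rng, caplog):
        tumor, normal = _cohort(rng, n_genes=10)
        tumor.iloc[0] = 0.0  # unexpressed everywhere -> flat after log
        normal.iloc[0] = 0.0
        with caplog.at_level("WARNING"):
            z = cross_normalize(tumor, normal)
        assert "g0" not in z.data.index and len(z.data) == 9

    def test_gene_intersection(self, rng):
        tumor, normal = _cohort(rng, n_genes=20)
        z = cross_normalize(tumor.iloc[:15], normal.iloc[5:])
        assert len(z.data) == 10


class TestMetagene:
    def test_single_gene_panel_equals_gene_z(self, rng):
        z = cross_normalize(*_cohort(rng))
        score = metagene_score(z, ["g3"])
        assert np.allclose(score, z.data.loc["g3"])

    def test_mean_over_panel(self, rng):
        z = cross_normalize(*_cohort(rng))
        panel = ["g1", "g2", "g5", "g7", "g9"]
        score = metagene_score(z, panel)
        assert np.allclose(score, z.data.loc[panel].mean(axis=0))

    def test_missing_members_logged_all_missing_raises(self, rng, caplog):
        z = cross_normalize(*_cohort(rng, n_genes=5))
        with caplog.at_level("WARNING"):
            metagene_score(z, ["g1", "ghost"])
        assert "ghost" in caplog.text
        with pytest.raises(ValueError):
            metagene_score(z, ["ghost"])


class TestRoc:
    def _labels(self, pos, neg):
        return pd.Series(["tumor"] * len(pos) + ["normal"] * len(neg),
                         index=[f"s{i}" for i in range(len(pos) + len(neg))])

    def _scores(self, pos, neg):
        return pd.Series(list(pos) + list(neg),
                         index=[f"s{i}" for i in range(len(pos) + len(neg))])

    def test_hand_example(self):
        res = roc_auc(self._scores([3, 5], [1, 4]), self._labels([3, 5], [1, 4]))
        assert res.auc == pytest.approx(0.75)  # 3 of 4 pairs concordant

    def test_all_ties_give_half(self):
        res = roc_auc(self._scores([1, 1, 1], [1, 1]), self._labels([1] * 3, [1] * 2))
        assert res.auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        res = roc_auc(self._scores([5, 6, 7], [1, 2]), self._labels([0] * 3, [0] * 2))
        assert res.auc == 1.0 and res.sensitivity == 1.0 and res.specificity == 1.0

    def test_pair_counting_equals_trapezoid(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.normal(size=n), 1)  # rounding forces ties
            scores = pd.Series(s, index=[f"s{i}" for i in range(n)])
            labels = pd.Series(np.where(y == 1, "tumor", "normal"), index=scores.index)
            assert roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(y, s), abs=1e-12
            )

    def test_antisymmetry(self, rng):
        s = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        labels = pd.Series(["tumor"] * 15 + ["normal"] * 25, index=s.index)
        assert roc_auc(s, labels).auc + roc_auc(-s, labels).auc == pytest.approx(1.0)

    def test_ci_brackets_auc(self, rng):
        s = pd.Series(rng.normal(size=60), index=[f"s{i}" for i in range(60)])
        s.iloc[:25] += 1.0
        labels = pd.Series(["tumor"] * 25 + ["normal"] * 35, index=s.index)
        res = roc_auc(s, labels)
        assert res.ci_low <= res.auc <= res.ci_high

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(self._scores([1, 2], []), self._labels([1, 2], []))


class TestRocByStage:
    def test_stage_equal_to_full_set_matches_pooled(self, rng):
        s = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        labels = pd.Series(["tumor"] * 20 + ["normal"] * 20, index=s.index)
        stages = pd.Series([1.0] * 20 + [np.nan] * 20, index=s.index)
        out = roc_by_stage(s, labels, stages)
        assert out["stage_1"].auc == pytest.approx(out["pooled"].auc)

    def test_down_panel_mirrors_up_panel(self, rng):
        s = pd.Series(np.concatenate([rng.normal(1.5, 1, 30), rng.normal(0, 1, 20)]),
                      index=[f"s{i}" for i in range(50)])
        labels = pd.Series(["tumor"] * 30 + ["normal"] * 20, index=s.index)
        up = roc_auc(s, labels)
        down = roc_auc(-s, labels)
        assert down.auc < 0.5
        assert 1 - down.auc == pytest.approx(up.auc)

    def test_sparse_stage_skipped(self, rng, caplog):
        s = pd.Series(rng.normal(size=24), index=[f"s{i}" for i in range(24)])
        labels = pd.Series(["tumor"] * 12 + ["normal"] * 12, index=s.index)
        stages = pd.Series([1.0] * 10 + [2.0] * 2 + [np.nan] * 12, index=s.index)
        with caplog.at_level("WARNING"):
            out = roc_by_stage(s, labels, stages)
        assert "stage_2" not in out and "skipped" in caplog.text

    def test_stage_uniform_effect_close_to_pooled(self, rng):
        n_t, n_n = 120, 60
        s = pd.Series(np.concatenate([rng.normal(1.2, 1, n_t), rng.normal(0, 1, n_n)]),
                      index=[f"s{i}" for i in range(n_t + n_n)])
        labels = pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=s.index)
        stages = pd.Series(list(rng.integers(1, 5, n_t).astype(float)) + [np.nan] * n_n,
                           index=s.index)
        out = roc_by_stage(s, labels, stages)
        for k, r in out.items():
            if k != "pooled":
                assert abs(r.auc - out["pooled"].auc) < 0.1


class TestSurvival:
    def test_identical_groups_null(self):
        # two groups with identical time/event patterns
        scores = pd.Series([1, 1, 1, 2, 2, 2], index=list("abcdef"), dtype=float)
        time = pd.Series([5, 10, 15, 5, 10, 15], index=list("abcdef"), dtype=float)
        event = pd.Series([1, 1, 0, 1, 1, 0], index=list("abcdef"))
        comp, _ = km_logrank(scores, time, event)
        assert comp.logrank_chi2 == pytest.approx(0.0, abs=1e-9)
        assert comp.p == pytest.approx(1.0)

    def test_toy_example_matches_hand_computation(self):
        # low group times (1,3,5) events (1,1,0); high group (2,4,6) all events.
        # Hand log-rank tally: O_high=3, E_high=3.266..., V=0.96222,
        # chi2=(O-E)^2/V = 0.07390, p = 0.7857
        scores = pd.Series([0, 0, 0, 1, 1, 1], index=list("abcdef"), dtype=float)
        time = pd.Series([1, 3, 5, 2, 4, 6], index=list("abcdef"), dtype=float)
        event = pd.Series([1, 1, 0, 1, 1, 1], index=list("abcdef"))
        comp, curves = km_logrank(scores, time, event)
        assert comp.logrank_chi2 == pytest.approx(0.07390, abs=1e-4)
        assert comp.p == pytest.approx(0.7857, abs=1e-3)
        assert comp.n_high == 3 and comp.n_low == 3
        assert set(curves) == {"high", "low"}
        assert (curves["high"]["survival"].diff().dropna() <= 0).all()

    def test_monotone_transform_invariance(self, rng):
        n = 40
        scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        time = pd.Series(rng.exponential(10, n), index=scores.index)
        event = pd.Series(rng.integers(0, 2, n), index=scores.index)
        c1, _ = km_logrank(scores, time, event, curves=False)
        c2, _ = km_logrank(np.exp(scores * 3), time, event, curves=False)
        assert c1.logrank_chi2 == pytest.approx(c2.logrank_chi2)

    def test_detects_planted_hazard(self, rng):
        from regulomics.synthetic_data import simulate_survival

        z = rng.normal(size=100)
        time, event = simulate_survival(z, beta=0.8, baseline_hazard=0.05,
                                        censor_max=40, rng=rng)
        idx = [f"s{i}" for i in range(100)]
        comp, _ = km_logrank(
            pd.Series(z, index=idx), pd.Series(time, index=idx),
            pd.Series(event, index=idx), curves=False,
        )
        assert comp.p < 0.05 and comp.direction == "high"

    def test_too_few_events_rejected(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0])
        time = pd.Series([1.0, 2.0, 3.0, 4.0])
        event = pd.Series([0, 0, 1, 0])
        with pytest.raises(ValueError, match="events"):
            km_logrank(scores, time, event)


class TestStrata:
    def test_two_group_case_matches_wilcoxon(self):
        rng = np.random.default_rng(5)
        n = 200
        scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        strata = pd.Series(["a"] * 100 + ["b"] * 100, index=scores.index)
        out = strata_compare(scores, strata)
        p_w = stats.mannwhitneyu(scores[:100], scores[100:],
                                 alternative="two-sided").pvalue
        assert abs(out["p"] - p_w) < 0.01  # asymptotically equivalent

    def test_planted_shift_detected(self, rng):
        scores = pd.Series(
            np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)]),
            index=[f"s{i}" for i in range(100)],
        )
        strata = pd.Series(["a"] * 50 + ["b"] * 50, index=scores.index)
        out = strata_compare(scores, strata)
        assert out["p"] < 0.01
        assert (out["pairwise"]["q"] < 0.01).all()

    def test_degenerate_strata_rejected(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        strata = pd.Series(["x", "x", "y"], index=list("abc"))
        with pytest.raises(ValueError):
            strata_compare(scores, strata)


class TestMulticancer:
    def _zcohort(self, rng, shift):
        tumor, normal = _cohort(rng, n_genes=30, shift_genes=[f"g{i}" for i in range(5)],
                                shift=shift)
        z = cross_normalize(tumor, normal)
        return z.data, z.labels

    def test_directions_and_significance(self, rng):
        cohorts = {
            "gastric": self._zcohort(rng, 2.0),
            "quiet": self._zcohort(rng, 0.0),
            "inverted": self._zcohort(rng, -2.0),
        }
        out = multicancer_panel(cohorts, [f"g{i}" for i in range(5)]).set_index("cohort")
        assert out.loc["gastric", "significant"] and out.loc["gastric", "direction"] == "up"
        assert out.loc["inverted", "direction"] == "down"
        assert not out.loc["quiet", "significant"]

    def test_duplicate_cohort_identical_statistics(self, rng):
        c = self._zcohort(rng, 1.5)
        out = multicancer_panel({"a": c, "b": c}, [f"g{i}" for i in range(5)])
        assert out["p"].nunique() == 1

    def test_cohort_missing_class_skipped(self, rng, caplog):
        data, labels = self._zcohort(rng, 1.0)
        tumor_only = labels[labels == "tumor"]
        with caplog.at_level("WARNING"):
            out = multicancer_panel(
                {"ok": (data, labels), "broken": (data[tumor_only.index], tumor_only)},
                [f"g{i}" for i in range(5)],
            )
        assert list(out["cohort"]) == ["ok"] and "skipped" in caplog.text
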
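import itertools

import numpy as np
import pandas as pd
import pytest

import dabench
from dabench import (
    cat_auc,
    cat_curve,
    enrichment_analysis,
    mock_labelings,
    mutual_findings,
    tp_fp_difference_curve,
    type_one_error_summary,
)
from dabench.methods import DAResult, _make_result


class TestMockLabelings:
    def test_group_sizes_41(self):
        labs = mock_labelings(41, 5, seed=0)
        for lab in labs:
            assert (lab == "group1").sum() == 21
            assert (lab == "group2").sum() == 20

    def test_small_n_distinct_splits(self):
        labs = mock_labelings(4, 3, seed=1)
        assert len({tuple(l) for l in labs}) == 3

    def test_seed_reproducibility(self):
        a = mock_labelings(10, 4, seed=7)
        b = mock_labelings(10, 4, seed=7)
        assert all((x == y).all() for x, y in zip(a, b))


class TestTypeOneError:
    def _register(self, name, pfun):
        def runner(ct, x, seed, **_):
            F = ct.n_features
            return _make_result(name, ct.feature_ids, np.ones(F), np.ones(F),
                                pfun(F))

        dabench.register_method(name, runner)

    def _cleanup(self, name):
        from dabench.methods import CATALOG, _PLUGINS
        _PLUGINS.pop(name)
        CATALOG.pop(name)

    def test_uniform_grid_p_values(self, sim_null):
        self._register("grid_p", lambda F: (np.arange(F) + 0.5) / F)
        try:
            summary, qq = type_one_error_summary(
                sim_null.table, ["grid_p"], B=3, seed=0
            )
            assert np.allclose(summary["fpr_0.05"], 0.05, atol=1 / 150)
            F = sim_null.table.n_features
            assert (summary["ks"] <= 0.5 / F + 1e-9).all()
        finally:
            self._cleanup("grid_p")

    def test_degenerate_conservative_test(self, sim_null):
        self._register("all_one_p", lambda F: np.ones(F))
        try:
            summary, _ = type_one_error_summary(
                sim_null.table, ["all_one_p"], B=2, seed=0
            )
            for a in (0.01, 0.05, 0.1):
                assert (summary[f"fpr_{a}"] == 0).all()
            assert (summary["ks"] > 0.95).all()  # ECDF mass entirely at 1
        finally:
            self._cleanup("all_one_p")

    def test_fpr_invariant_to_group_relabeling(self, sim_null):
        ct = sim_null.table
        labels = np.array(["group1"] * 20 + ["group2"] * 20, dtype=object)
        swapped = np.where(labels == "group1", "zgroup", "agroup")
        r1 = dabench.run_da(ct, labels, "wilcoxon_tss")
        r2 = dabench.run_da(ct, swapped, "wilcoxon_tss")
        p1 = r1.table["raw_p"].dropna()
        p2 = r2.table["raw_p"].dropna()
        assert np.allclose(p1, p2)


class TestCAT:
    def test_identical_lists(self):
        c = cat_curve(list("abcde"), list("abcde"), R=5)
        assert np.allclose(c.values, 1.0)
        assert cat_auc(c) == 1.0

    def test_reversed_halves(self):
        ids = [f"f{i}" for i in range(10)]
        c = cat_curve(ids, ids[::-1], R=10)
        assert c.values[4] == 0.0  # disjoint top halves
        assert c.values[9] == 1.0  # full universe

    def test_small_enumeration(self):
        c = cat_curve(["a", "b", "c"], ["b", "a", "c"], R=3)
        assert np.allclose(c.values, [0.0, 1.0, 1.0])
        assert np.isclose(cat_auc(c), 2.0 / 3.0)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cat_curve(["a", "a", "b"], ["a", "b", "b"], R=2)

    def test_truncation_beyond_universe(self):
        c = cat_curve(list("abc"), list("cab"), R=5)
        assert c.truncated
        assert np.isnan(c.values[3:]).all()
        assert np.isfinite(cat_auc(c))

    def test_brute_force_oracle_on_permutations(self):
        ids = list("abcde")
        for pa, pb in itertools.islice(
            itertools.product(itertools.permutations(ids), repeat=2), 60
        ):
            c = cat_curve(list(pa), list(pb), R=5)
            brute = [
                len(set(pa[: i + 1]) & set(pb[: i + 1])) / (i + 1) for i in range(5)
            ]
            assert np.allclose(c.values, brute)

    def test_random_ranking_expectation(self):
        # E[C_i] = i/F for independent uniform rankings (hypergeometric)
        rng = np.random.default_rng(5)
        F, R, reps = 60, 20, 300
        ids = [f"f{i}" for i in range(F)]
        acc = np.zeros(R)
        for _ in range(reps):
            acc += cat_curve(list(rng.permutation(ids)),
                             list(rng.permutation(ids)), R=R).values
        mean = acc / reps
        expect = np.arange(1, R + 1) / F
        se = np.sqrt(expect * (1 - expect) / (np.arange(1, R + 1) * reps)) + 1e-3
        assert np.all(np.abs(mean - expect) < 4 * se)


class TestConcordance:
    def test_deterministic_plugin_has_perfect_wmc(self, sim_null):
        def by_id(ct, x, seed, **_):
            F = ct.n_features
            p = np.linspace(0.01, 0.99, F)  # fixed order = feature order
            return _make_result("by_id", ct.feature_ids, np.ones(F), np.ones(F), p)

        dabench.register_method("rank_by_id", by_id)
        dabench.register_method("rank_by_id2", by_id)
        try:
            wmc, bmc, failed = dabench.concordance_analysis(
                sim_null.table, sim_null.table.sample_meta["group"],
                ["rank_by_id", "rank_by_id2"], n_splits=2, R=20, seed=0,
            )
            assert np.isclose(wmc["rank_by_id"], 1.0)
            assert np.isclose(bmc.loc["rank_by_id", "rank_by_id2"], 1.0)
            assert np.isclose(bmc.loc["rank_by_id2", "rank_by_id"], 1.0)
        finally:
            from dabench.methods import CATALOG, _PLUGINS
            for name in ("rank_by_id", "rank_by_id2"):
                _PLUGINS.pop(name)
                CATALOG.pop(name)

    def test_subject_dedup_keeps_one_sample_each(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(20, size=(30, 16)),
                              columns=[f"s{j}" for j in range(16)])
        meta = pd.DataFrame({
            "subject_id": [f"subj{j % 8}" for j in range(16)],
            "group": ["g1", "g2"] * 8,
        }, index=counts.columns)
        ct = dabench.CountTable(counts, sample_meta=meta)
        from dabench.evaluation import _dedup_subjects
        out = _dedup_subjects(ct, np.random.default_rng(0))
        assert out.n_samples == 8
        assert out.sample_meta["subject_id"].is_unique


class TestEnrichment:
    def _result(self, ann_index, da_up):
        F = len(ann_index)
        p = np.where(np.isin(ann_index, da_up), 1e-6, 0.9)
        coef = np.where(np.isin(ann_index, da_up), 2.0, 0.5)
        return _make_result("toy", ann_index, coef, coef, p)

    def test_haldane_anscombe_log_or(self):
        # contingency [[10, 0], [5, 5]] -> HA OR = (10.5 * 5.5)/(0.5 * 5.5) = 21
        feats = [f"f{i}" for i in range(20)]
        ann = pd.Series(["aerobic"] * 10 + ["anaerobic"] * 10, index=feats)
        res = self._result(np.array(feats), feats[:10] + feats[10:15])
        e = enrichment_analysis(res, ann, alpha=0.1)
        row = e[(e["class"] == "aerobic") & (e["direction"] == "UP")].iloc[0]
        assert row["count"] == 10
        assert np.isclose(row["log_or"], np.log(21.0))

    def test_empty_da_set_gives_unit_p(self, annotations_150):
        feats = annotations_150.index.to_numpy()
        res = _make_result("toy", feats, np.ones(len(feats)),
                           np.ones(len(feats)), np.full(len(feats), 0.9))
        e = enrichment_analysis(res, annotations_150, alpha=0.1)
        assert (e["fisher_p"] == 1.0).all()
        assert (e["count"] == 0).all()

    def test_aerobic_up_enrichment_detected(self):
        feats = [f"f{i}" for i in range(40)]
        ann = pd.Series(["aerobic"] * 10 + ["anaerobic"] * 30, index=feats)
        res = self._result(np.array(feats), feats[:10])  # every aerobic is UP-DA
        e = enrichment_analysis(res, ann, alpha=0.1)
        up = e.set_index(["class", "direction"])
        assert up.loc[("aerobic", "UP"), "fisher_p"] < 0.05
        assert up.loc[("anaerobic", "UP"), "fisher_p"] == 1.0

    def test_cells_cover_annotated_universe(self, annotations_150, sim_strong):
        res = dabench.run_da(sim_strong.table,
                             sim_strong.table.sample_meta["group"],
                             "moderated_t_tmm")
        e = enrichment_analysis(res, annotations_150)
        n_annotated = annotations_150.isin(
            ["aerobic", "anaerobic", "facultative"]
        ).sum()
        # for each test, count <= class size and the implied margins match
        assert (e["count"] >= 0).all()
        assert e["count"].max() <= n_annotated


class TestTpFp:
    def test_perfect_and_antiperfect_ranking(self):
        feats = [f"f{i}" for i in range(30)]
        ann = pd.Series(["aerobic"] * 15 + ["anaerobic"] * 15, index=feats)
        p = np.linspace(1e-6, 0.9, 30)
        coef = np.concatenate([np.full(15, 2.0), np.full(15, -2.0)])
        res = _make_result("toy", feats, coef, np.abs(coef), p)
        curve = tp_fp_difference_curve(res, ann)
        assert (np.diff(curve["tp_minus_fp"]) >= 0).all()
        anti = _make_result("toy", feats, -coef, np.abs(coef), p)
        anti_curve = tp_fp_difference_curve(anti, ann)
        assert (anti_curve["tp_minus_fp"] == -curve["tp_minus_fp"]).all()

    def test_random_ranking_mean_near_zero(self):
        rng = np.random.default_rng(8)
        feats = [f"f{i}" for i in range(100)]
        ann = pd.Series(["aerobic"] * 50 + ["anaerobic"] * 50, index=feats)
        diffs = []
        for _ in range(60):
            p = rng.permutation(np.linspace(0.001, 0.999, 100))
            coef = rng.choice([-1.0, 1.0], size=100)
            res = _make_result("toy", feats, coef, np.abs(coef), p)
            curve = tp_fp_difference_curve(res, ann, thresholds=[0.2])
            diffs.append(curve["tp_minus_fp"].iloc[0])
        assert abs(np.mean(diffs)) < 1.0  # E = 0, SE ~ 0.4


class TestMutualFindings:
    def _res(self, feats, da):
        p = np.where(np.isin(feats, da), 1e-4, 0.9)
        return _make_result("toy", feats, np.ones(len(feats)),
                            np.ones(len(feats)), p)

    def test_intersection_count(self):
        feats = np.array(["a", "b", "c", "d"])
        results = [self._res(feats, ["a", "b"]), self._res(feats, ["b", "c"]),
                   self._res(feats, ["b"])]
        found = mutual_findings(results, "UP", min_methods=2)
        assert list(found.index) == ["b"]
        assert found["b"] == 3

    def test_min_one_gives_union(self):
        feats = np.array(["a", "b", "c", "d"])
        results = [self._res(feats, ["a"]), self._res(feats, ["c"])]
        found = mutual_findings(results, "UP", min_methods=1)
        assert set(found.index) == {"a", "c"}

    def test_unanimous_feature(self):
        feats = np.array(["a", "b", "c"])
        results = [self._res(feats, ["a"]) for _ in range(4)]
        found = mutual_findings(results, "UP", min_methods=4)
        assert list(found.index) == ["a"]
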
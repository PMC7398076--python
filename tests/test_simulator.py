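import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dabench
from dabench import (
    SimulationDesign,
    apply_sparsity_effect,
    builtin_template,
    estimate_template,
    inject_da,
    power_evaluation,
    simulate_dataset,
)
from dabench.methods import _make_result


class TestTemplates:
    def test_relative_means_positive_and_normalized(self):
        for kind in ("16s", "wms"):
            tpl = builtin_template(kind, n_features=200)
            assert (tpl.relative_means > 0).all()
            assert abs(tpl.relative_means.sum() - 1.0) < 1e-12

    def test_sparsity_regimes(self):
        sim16 = simulate_dataset(SimulationDesign(distribution="NB", seed=0),
                                 builtin_template("16s"), 0, inject=False)
        z16 = dabench.zero_fraction(sim16.table)[0]
        assert 0.55 <= z16 <= 0.83
        tplw = builtin_template("wms")
        simw = simulate_dataset(SimulationDesign(distribution="ZINB", seed=0),
                                tplw, 0, inject=False)
        zw = dabench.zero_fraction(simw.table)[0]
        assert 0.35 <= zw <= 0.89
        assert simw.table.library_sizes.min() >= 1e6

    def test_parameter_recovery(self):
        # moderate-spread composition: no single taxon dominates the library
        # totals, so the offset-based ML estimate is free of compositional
        # feedback and recovery reflects pure sampling noise
        rng = np.random.default_rng(2)
        r = np.exp(rng.normal(0, 1.5, 100))
        r /= r.sum()
        tpl = dabench.TemplateParams(
            r, dispersion=1.2, zero_inflation=None,
            library_sizes=np.full(50, 5000.0), distribution="NB",
        )
        design = SimulationDesign(distribution="NB", n_per_group=100, seed=3)
        sim = simulate_dataset(design, tpl, 0, inject=False)
        est = estimate_template(sim.table, "NB")
        depth = sim.table.library_sizes.to_numpy().sum()
        good = tpl.relative_means > 10.0 / depth
        rel_err = np.abs(est.relative_means - tpl.relative_means) / tpl.relative_means
        assert good.sum() >= 10
        assert np.median(rel_err[good]) < 0.10

    def test_heavy_tailed_recovery_is_compositionally_distorted(self):
        # documented limitation: when one taxon holds ~40% of the reads, its
        # noise feeds back through the realized library sizes and recovery of
        # the dominant features degrades — the estimate stays in the right
        # order of magnitude but is no longer within pure-sampling precision
        tpl = builtin_template("16s", n_features=100)
        design = SimulationDesign(distribution="NB", n_per_group=100, seed=3)
        sim = simulate_dataset(design, tpl, 0, inject=False)
        est = estimate_template(sim.table, "NB")
        good = tpl.relative_means > 2e-3
        rel_err = np.abs(est.relative_means - tpl.relative_means) / tpl.relative_means
        assert np.median(rel_err[good]) < 0.5

    def test_zinb_template_on_zero_free_data_has_no_inflation(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(60, size=(50, 40)) + 1
        ct = dabench.CountTable(pd.DataFrame(
            counts, index=[f"f{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(40)]))
        est = estimate_template(ct, "ZINB")
        assert np.all(est.zero_inflation < 1e-2)


class TestInjection:
    def test_compensation_conserves_flagged_mass(self):
        tpl = builtin_template("16s", n_features=250)
        for seed in range(20):
            r1, r2, truth = inject_da(tpl, 0.1, 5.0, compensation=True, seed=seed)
            flagged = truth["is_da"].to_numpy()
            raw = truth.attrs["r2_unnormalized"]
            assert np.isclose(raw[flagged].sum(), r1[flagged].sum(), rtol=1e-12)
            assert abs(r2.sum() - 1.0) < 1e-12
            # unflagged features untouched after renormalization
            assert np.allclose(r2[~flagged], r1[~flagged], rtol=1e-9)

    def test_fold_ratio_without_compensation(self):
        tpl = builtin_template("16s", n_features=250)
        r1, r2, truth = inject_da(tpl, 0.1, 2.0, compensation=False, seed=4)
        raw = truth.attrs["r2_unnormalized"]
        up = (truth["direction"] == "up").to_numpy()
        down = (truth["direction"] == "down").to_numpy()
        assert np.allclose(raw[up] / r1[up], 2.0, rtol=1e-12)
        assert np.allclose(raw[down] / r1[down], 0.5, rtol=1e-12)

    def test_flag_count_rounding(self):
        tpl = builtin_template("16s", n_features=250)
        _, _, truth = inject_da(tpl, 0.10, 2.0, seed=0)
        assert truth["is_da"].sum() == 25

    def test_degenerate_proportion_rejected(self):
        tpl = builtin_template("16s", n_features=10)
        with pytest.raises(ValueError, match="< 2"):
            inject_da(tpl, 0.05, 2.0, seed=0)


class TestSparsityEffect:
    def _truth(self, tpl, directions):
        return pd.DataFrame(
            {"is_da": [d != "" for d in directions], "direction": directions},
            index=pd.Index(tpl.feature_ids),
        )

    def test_no_effect_leaves_pi_unchanged(self):
        tpl = builtin_template("wms", n_features=5)
        truth = self._truth(tpl, ["up", "down", "", "", ""])
        pi1, pi2 = apply_sparsity_effect(tpl, truth, 0.0)
        assert np.allclose(pi2, tpl.zero_inflation)

    def test_shift_and_clamp(self):
        tpl = builtin_template("wms", n_features=3)
        tpl.zero_inflation[:] = [0.99, 0.5, 0.3]
        truth = self._truth(tpl, ["down", "up", ""])
        pi1, pi2 = apply_sparsity_effect(tpl, truth, 0.05)
        assert pi2[0] == 1.0  # 0.99 + 0.05 clamped ("forced to the closer limit")
        assert np.isclose(pi2[1], 0.45)
        assert pi2[2] == 0.3
        pi1b, pi2b = apply_sparsity_effect(tpl, self._truth(tpl, ["", "up", ""]), 0.15)
        assert np.isclose(pi2b[1], 0.5 - 0.15)

    def test_nb_design_forces_zero_sparsity(self):
        d = SimulationDesign(distribution="NB", sparsity_effect=0.15)
        assert d.sparsity_effect == 0.0


class TestSimulateDataset:
    def test_reproducible_counts(self):
        tpl = builtin_template("16s", n_features=80)
        d = SimulationDesign(distribution="NB", n_per_group=10, seed=5)
        a = simulate_dataset(d, tpl, replicate_index=3)
        b = simulate_dataset(d, tpl, replicate_index=3)
        pd.testing.assert_frame_equal(a.table.counts, b.table.counts)
        c = simulate_dataset(d, tpl, replicate_index=4)
        assert not a.table.counts.equals(c.table.counts)

    def test_null_dataset_has_equal_group_means(self):
        tpl = builtin_template("16s", n_features=100)
        d = SimulationDesign(distribution="NB", n_per_group=20, seed=6)
        pvals = []
        means1, means2 = [], []
        for rep in range(25):
            sim = simulate_dataset(d, tpl, rep, inject=False)
            Y = sim.table.matrix().astype(float)
            means1.append(Y[:, :20].mean(1))
            means2.append(Y[:, 20:].mean(1))
        m1 = np.array(means1)
        m2 = np.array(means2)
        _, p = stats.ttest_rel(m1, m2, axis=0)
        assert (p > 0.05).mean() >= 0.90

    def test_zinb_with_zero_inflation_off_matches_nb(self):
        tpl_nb = builtin_template("16s", n_features=100)
        tpl_zi = builtin_template("16s", n_features=100)
        tpl_zi.distribution = "ZINB"
        tpl_zi.zero_inflation = np.zeros(100)
        zf_nb, zf_zi = [], []
        for rep in range(15):
            d_nb = SimulationDesign(distribution="NB", n_per_group=15, seed=8)
            d_zi = SimulationDesign(distribution="ZINB", n_per_group=15, seed=8)
            zf_nb.append(dabench.zero_fraction(
                simulate_dataset(d_nb, tpl_nb, rep, inject=False).table)[0])
            zf_zi.append(dabench.zero_fraction(
                simulate_dataset(d_zi, tpl_zi, rep, inject=False).table)[0])
        # degenerate mixture: same zero fraction up to Monte-Carlo noise
        se = np.std(zf_nb, ddof=1) / np.sqrt(len(zf_nb))
        assert abs(np.mean(zf_nb) - np.mean(zf_zi)) < 4 * se + 0.01

    def test_truth_fraction_matches_design(self):
        tpl = builtin_template("16s", n_features=200)
        d = SimulationDesign(distribution="NB", da_proportion=0.5, seed=9)
        sim = simulate_dataset(d, tpl, 0)
        assert sim.truth["is_da"].sum() == 100


class TestPowerEvaluation:
    def _sims(self, n=3):
        tpl = builtin_template("16s", n_features=60)
        d = SimulationDesign(distribution="NB", n_per_group=10,
                             fold_effect=5.0, seed=10)
        return [simulate_dataset(d, tpl, r) for r in range(n)]

    def test_oracle_method_is_perfect(self):
        sims = self._sims()

        def oracle(ct, x, seed, **_):
            truth = sims_by_id[id(ct)]
            p = np.where(truth, 0.0, 1.0)
            return _make_result("oracle", ct.feature_ids, p * 0 + 1.0,
                                np.ones(len(p)), p)

        sims_by_id = {id(s.table): s.truth["is_da"].to_numpy() for s in sims}
        dabench.register_method("oracle", oracle)
        try:
            rep = power_evaluation(sims, ["oracle"], alpha=0.05)
            assert np.isclose(rep.loc["oracle", "tpr"], 1.0)
            assert np.isclose(rep.loc["oracle", "fpr"], 0.0)
            assert np.isclose(rep.loc["oracle", "pauroc_raw"], 0.1)
            assert np.isclose(rep.loc["oracle", "pauroc_norm"], 1.0)
        finally:
            from dabench.methods import CATALOG, _PLUGINS
            _PLUGINS.pop("oracle")
            CATALOG.pop("oracle")

    def test_coin_flip_ranking_near_chance(self):
        sims = self._sims(n=20)
        state = {"i": 0}

        def coin(ct, x, seed, **_):
            rng = np.random.default_rng(seed)
            p = rng.random(ct.n_features)
            return _make_result("coin", ct.feature_ids, np.ones(len(p)),
                                np.ones(len(p)), p)

        dabench.register_method("coinflip", coin)
        try:
            rep = power_evaluation(sims, ["coinflip"], alpha=0.05, seed=2)
            # chance area under the diagonal on [0, 0.1] is 0.005 -> norm 0.05
            assert abs(rep.loc["coinflip", "pauroc_norm"] - 0.05) < 0.04
        finally:
            from dabench.methods import CATALOG, _PLUGINS
            _PLUGINS.pop("coinflip")
            CATALOG.pop("coinflip")

    def test_strong_signal_method_beats_chance(self):
        sims = self._sims(n=3)
        rep = power_evaluation(sims, ["moderated_t_tmm"], alpha=0.05)
        assert rep.loc["moderated_t_tmm", "pauroc_norm"] > 0.3
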
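"""W statistics, the data-dependent threshold and the selection pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import knockboost as kb


def brute_force_threshold(w, q, offset):
    """Exhaustive search over positive candidate thresholds."""
    best = np.inf
    for t in np.unique(np.abs(w[w != 0])):
        if (offset + np.sum(w <= -t)) / max(1, np.sum(w >= t)) <= q:
            best = min(best, t)
    return best


class TestComputeW:
    def test_shap_diff_arithmetic(self):
        z = np.array([0.5, 0.2, 0.1, 0.3])
        w = kb.compute_w(z, kind="shap_diff")
        assert np.allclose(w.w, [0.4, -0.1])

    def test_signed_max_arithmetic(self):
        z = np.array([0.5, 0.2, 0.1, 0.3])
        w = kb.compute_w(z, kind="shap_signed_max")
        assert np.allclose(w.w, [0.5, -0.3])

    @pytest.mark.parametrize("kind", ["shap_diff", "shap_signed_max"])
    def test_ties_give_zero(self, kind):
        z = np.array([0.4, 0.7, 0.4, 0.7])
        assert np.allclose(kb.compute_w(z, kind=kind).w, 0.0)

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError, match="even"):
            kb.compute_w(np.array([1.0, 2.0, 3.0]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=40),
           st.sampled_from(["shap_diff", "shap_signed_max"]))
    def test_flip_sign_property(self, zs, kind):
        """Swapping any original/knockoff pair negates exactly that W_j."""
        if len(zs) % 2:
            zs = zs + [0.0]
        z = np.array(zs)
        p = z.size // 2
        w = kb.compute_w(z, kind=kind).w
        for j in range(p):
            swapped = z.copy()
            swapped[j], swapped[j + p] = swapped[j + p], swapped[j]
            ws = kb.compute_w(swapped, kind=kind).w
            assert ws[j] == pytest.approx(-w[j], abs=1e-12)
            mask = np.arange(p) != j
            assert np.allclose(ws[mask], w[mask])


class TestThreshold:
    def test_worked_example_knockoff_plus(self):
        w = np.array([3.0, 2.0, -1.0, 1.0])
        tau = kb.knockoff_threshold(w, q=0.5, offset=1)
        assert tau == 2.0
        sel = kb.select(kb.WStatistics(w, "shap_diff"), tau)
        assert sel.selected == [0, 1]

    def test_all_negative_gives_empty_selection(self):
        w = np.array([-1.0, -2.0])
        tau = kb.knockoff_threshold(w, q=0.5)
        assert np.isinf(tau)
        assert kb.select(kb.WStatistics(w, "shap_diff"), tau).selected == []

    def test_offset_zero_variant(self):
        tau = kb.knockoff_threshold(np.array([5.0]), q=0.999, offset=0)
        assert tau == 5.0

    def test_q_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="q"):
            kb.knockoff_threshold(np.array([1.0]), q=1.0)

    def test_agrees_with_exhaustive_search(self):
        """1000 random W vectors, p <= 50, both offsets."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.integers(1, 51)
            w = np.round(rng.standard_normal(p), 2)
            q = rng.uniform(0.05, 0.5)
            offset = int(rng.integers(0, 2))
            assert kb.knockoff_threshold(w, q, offset) == brute_force_threshold(w, q, offset)

    def test_monotonicity_in_q(self):
        rng = np.random.default_rng(1)
        w = kb.WStatistics(rng.standard_normal(80), "shap_diff")
        sizes = []
        for q in (0.05, 0.1, 0.2, 0.4):
            tau = kb.knockoff_threshold(w, q)
            sizes.append(len(kb.select(w, tau).selected))
        assert sizes == sorted(sizes)

    def test_all_positive_smallest_threshold_selects_all(self):
        w = kb.WStatistics(np.array([0.5, 1.0, 2.0]), "shap_diff")
        sel = kb.select(w, 0.5)
        assert sel.selected == [0, 1, 2]


class TestLassoPathStatistic:
    def test_dominant_signal_enters_first(self):
        rng = np.random.default_rng(2)
        x = kb.DesignMatrix(rng.normal(size=(200, 5)))
        cov = kb.estimate_covariance(x)
        kmod = kb.sample_knockoffs(x, cov, kb.solve_s_equi(cov), seed=0)
        y = x.values[:, 0].copy()
        z = kb.lasso_path_statistic(x, kmod, y)
        assert np.argmax(z.z) == 0
        assert np.all(z.z >= 0)

    def test_noise_gives_smaller_entry_points(self):
        rng = np.random.default_rng(3)
        x = kb.DesignMatrix(rng.normal(size=(300, 5)))
        cov = kb.estimate_covariance(x)
        kmod = kb.sample_knockoffs(x, cov, kb.solve_s_equi(cov), seed=0)
        z_sig = kb.lasso_path_statistic(x, kmod, x.values[:, 0] * 3).z
        z_noise = kb.lasso_path_statistic(x, kmod, rng.normal(size=300)).z
        assert z_noise.max() < z_sig.max()

    def test_binary_path(self):
        rng = np.random.default_rng(4)
        x = kb.DesignMatrix(rng.normal(size=(200, 4)))
        cov = kb.estimate_covariance(x)
        kmod = kb.sample_knockoffs(x, cov, kb.solve_s_equi(cov), seed=0)
        y = (x.values[:, 1] > 0).astype(float)
        z = kb.lasso_path_statistic(x, kmod, y, task="binary")
        assert np.argmax(z.z) == 1


class TestRunPipeline:
    def test_planted_signal_recovered_small_scale(self):
        scen = kb.SimulationScenario(kind="lin_reg", n=400, p=100)
        x = kb.draw_design(scen, seed=0)
        y = kb.gen_response(scen, x, seed=1)
        res = kb.run_pipeline(x, y, q=0.1, seed=0)
        hits = len(set(res.selected) & set(range(10)))
        assert hits >= 9
        assert all(res.w.w[j] >= res.threshold for j in res.selected)

    def test_pure_noise_rarely_selects(self):
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = kb.DesignMatrix(rng.normal(size=(150, 60)))
            y = rng.normal(size=150)
            res = kb.run_pipeline(x, y, q=0.1, seed=seed)
            empty += not res.selected
        assert empty >= 16  # >= 80% of null runs stay empty

    def test_determinism_and_provenance(self):
        scen = kb.SimulationScenario(kind="lin_reg", n=200, p=50)
        x = kb.draw_design(scen, seed=5)
        y = kb.gen_response(scen, x, seed=6)
        r1 = kb.run_pipeline(x, y, q=0.2, seed=7)
        r2 = kb.run_pipeline(x, y, q=0.2, seed=7)
        assert r1.selected == r2.selected
        assert np.array_equal(r1.w.w, r2.w.w)
        assert r1.threshold == r2.threshold
        assert set(r1.stage_seconds) >= {"estimate_covariance", "fit_booster", "compute_w"}

    def test_full_pipeline_flip_sign_on_refit(self):
        """Swapping a pair's columns before the (deterministic) refit negates W_j."""
        scen = kb.SimulationScenario(kind="lin_reg", n=300, p=20)
        x = kb.draw_design(scen, seed=8)
        y = kb.gen_response(scen, x, seed=9)
        cov = kb.estimate_covariance(x)
        kmod = kb.sample_knockoffs(x, cov, kb.solve_s_equi(cov), seed=3)
        aug = kb.augment(x, kmod)
        cfg = kb.default_config("regression")
        # every tree must see every column: subsampling is index-dependent,
        # so swap-equivariance of the refit requires feature_fraction = 1
        cfg.hyperparameters["feature_fraction"] = 1.0

        def w_from(values):
            a = kb.AugmentedDesign(values, aug.pairing)
            model = kb.fit_booster(a, y, cfg)
            z = kb.aggregate_importance(kb.compute_attributions(model, a))
            return kb.compute_w(z).w

        w0 = w_from(aug.values)
        j = 0
        swapped = aug.values.copy()
        swapped[:, [j, j + 20]] = swapped[:, [j + 20, j]]
        w1 = w_from(swapped)
        assert w1[j] == pytest.approx(-w0[j], abs=1e-9)

    def test_stage_errors_are_tagged(self):
        x = kb.DesignMatrix(np.random.default_rng(0).normal(size=(50, 5)))
        y = np.zeros(50)  # single class once inferred binary-ish -> regression fallback
        with pytest.raises((RuntimeError, ValueError)):
            kb.run_pipeline(x, np.full(50, np.nan), q=0.1, seed=0)
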
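"""Observer-model operations against independent numerical oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from flashbeep import bci_core
from flashbeep.bci_core import (
    CONDITIONS,
    BCIParams,
    compute_estimates,
    fused_estimate,
    nearest_button,
    posterior_common,
    predict_condition_distribution,
    segregated_estimate,
    simulate_trials,
)

GRID = np.linspace(-60, 60, 240001)  # dense latent-count grid for oracles


def oracle_posterior(x_a, x_v, p: BCIParams) -> float:
    """Quadrature over the latent count N on a fine grid."""
    f1 = (
        stats.norm.pdf(x_a, GRID, p.sigma_a)
        * stats.norm.pdf(x_v, GRID, p.sigma_v)
        * stats.norm.pdf(GRID, p.mu_p, p.sigma_p)
    )
    l1 = np.trapezoid(f1, GRID)
    la = np.trapezoid(
        stats.norm.pdf(x_a, GRID, p.sigma_a) * stats.norm.pdf(GRID, p.mu_p, p.sigma_p),
        GRID,
    )
    lv = np.trapezoid(
        stats.norm.pdf(x_v, GRID, p.sigma_v) * stats.norm.pdf(GRID, p.mu_p, p.sigma_p),
        GRID,
    )
    num = p.p_common * l1
    return num / (num + (1 - p.p_common) * la * lv)


def oracle_map_common(x_a, x_v, p: BCIParams) -> float:
    """Grid argmax of the common-cause posterior density over N."""
    logpost = (
        stats.norm.logpdf(x_a, GRID, p.sigma_a)
        + stats.norm.logpdf(x_v, GRID, p.sigma_v)
        + stats.norm.logpdf(GRID, p.mu_p, p.sigma_p)
    )
    return GRID[np.argmax(logpost)]


class TestPosteriorCommon:
    def test_degenerate_priors(self):
        p1 = BCIParams(1.0, 2, 2, 0.5, 1)
        p0 = BCIParams(0.0, 2, 2, 0.5, 1)
        assert posterior_common(3.1, 0.2, p1) == 1.0
        assert posterior_common(3.1, 0.2, p0) == 0.0

    def test_matches_quadrature_oracle(self):
        p = BCIParams(0.5, 2, 2, 0.5, 1)
        assert posterior_common(2.0, 2.0, p) == pytest.approx(
            oracle_posterior(2.0, 2.0, p), abs=1e-6
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_sweep(self, seed):
        """Random parameter/sample points agree with quadrature to 1e-6."""
        rng = np.random.default_rng(seed)
        for _ in range(5):
            p = BCIParams(
                rng.uniform(0.05, 0.95),
                rng.uniform(1, 4),
                rng.uniform(0.5, 4),
                rng.uniform(0.3, 2),
                rng.uniform(0.3, 2),
            )
            x_a, x_v = rng.uniform(-1, 6, 2)
            assert posterior_common(x_a, x_v, p) == pytest.approx(
                oracle_posterior(x_a, x_v, p), abs=1e-6
            )

    def test_rejects_nonfinite_samples(self):
        p = BCIParams(0.5, 2, 2, 0.5, 1)
        with pytest.raises(ValueError):
            posterior_common(np.nan, 1.0, p)

    def test_complementarity_and_disparity_monotonicity(self):
        p = BCIParams(0.4, 2.5, 2, 0.6, 1.2)
        deltas = np.linspace(0, 4, 9)
        posts = [posterior_common(2 - d / 2, 2 + d / 2, p) for d in deltas]
        assert np.all(np.diff(posts) < 0)
        assert all(0 < q < 1 for q in posts)


class TestEstimates:
    def test_fused_all_sources_agree(self):
        p = BCIParams(0.5, 2, 2, 0.5, 1)
        assert fused_estimate(2.0, 2.0, p) == pytest.approx(2.0)

    def test_fused_equal_weights_is_mean(self):
        p = BCIParams(0.5, 1.0, 1.5, 1.5, 1.5)
        assert fused_estimate(1.0, 4.0, p) == pytest.approx(2.0)

    def test_fused_matches_map_oracle(self):
        p = BCIParams(0.42, 2.26, 2.34, 0.53, 1.11)
        assert fused_estimate(4.0, 1.0, p) == pytest.approx(
            oracle_map_common(4.0, 1.0, p), abs=1e-4
        )

    def test_segregated_identity_and_flat_prior(self):
        p = BCIParams(0.5, 2, 2, 0.5, 1)
        assert segregated_estimate(2.0, 0.5, p) == pytest.approx(2.0)
        flat = BCIParams(0.5, 2, 1e6, 0.5, 1)
        assert segregated_estimate(3.7, 0.5, flat) == pytest.approx(3.7, abs=1e-6)

    def test_segregated_matches_map_oracle(self):
        p = BCIParams(0.5, 2, 2, 0.5, 1)
        logpost = stats.norm.logpdf(3.0, GRID, 0.5) + stats.norm.logpdf(GRID, 2, 2)
        # tolerance = the oracle's grid spacing
        assert segregated_estimate(3.0, 0.5, p) == pytest.approx(
            GRID[np.argmax(logpost)], abs=5e-4
        )

    def test_estimates_within_input_hull(self):
        p = BCIParams(0.5, 2.0, 1.5, 0.6, 1.2)
        rng = np.random.default_rng(3)
        x_a = rng.uniform(-1, 6, 200)
        x_v = rng.uniform(-1, 6, 200)
        est = compute_estimates(x_a, x_v, p, "A")
        lo = np.minimum.reduce([x_a, x_v, np.full_like(x_a, p.mu_p)])
        hi = np.maximum.reduce([x_a, x_v, np.full_like(x_a, p.mu_p)])
        for arr in (est.n_fused, est.n_final):
            assert np.all(arr >= lo - 1e-9) and np.all(arr <= hi + 1e-9)
        assert np.all((est.post_common >= 0) & (est.post_common <= 1))


class TestDecisionStrategies:
    def test_forced_fusion_and_segregation_limits(self):
        for task, attr in (("A", "n_aud_seg"), ("V", "n_vis_seg")):
            p1 = BCIParams(1.0, 2, 2, 0.5, 1)
            e1 = compute_estimates(3.0, 1.0, p1, task)
            assert e1.n_final == pytest.approx(e1.n_fused)
            p0 = BCIParams(0.0, 2, 2, 0.5, 1)
            e0 = compute_estimates(3.0, 1.0, p0, task)
            assert e0.n_final == pytest.approx(getattr(e0, attr))

    def test_model_averaging_midpoint_at_symmetric_posterior(self):
        # symmetric construction: equal sigmas and symmetric samples around
        # mu_p give a posterior of whatever value; force 0.5 via prior choice
        p = BCIParams(0.5, 2, 2, 0.6, 0.6)
        x_a, x_v = 3.0, 1.0
        post = float(posterior_common(x_a, x_v, p))
        pc = 1 / (1 + (post / (1 - post)) / (p.p_common / (1 - p.p_common)))
        # choose the prior that moves this sample's posterior exactly to 0.5
        p_mid = p.with_(p_common=pc)
        e = compute_estimates(x_a, x_v, p_mid, "A")
        assert e.post_common == pytest.approx(0.5, abs=1e-12)
        assert e.n_final == pytest.approx(0.5 * (e.n_fused + e.n_aud_seg))

    def test_model_selection_threshold_and_tie(self):
        p = BCIParams(0.5, 2, 2, 0.6, 0.6, strategy="model_selection")
        rng = np.random.default_rng(0)
        x_a = rng.uniform(0, 5, 500)
        x_v = rng.uniform(0, 5, 500)
        e = compute_estimates(x_a, x_v, p, "A")
        sel_fused = e.post_common > 0.5
        assert np.allclose(e.n_final[sel_fused], e.n_fused[sel_fused])
        assert np.allclose(e.n_final[~sel_fused], e.n_aud_seg[~sel_fused])

    def test_probability_matching_requires_rng(self):
        p = BCIParams(0.5, 2, 2, 0.5, 1, strategy="probability_matching")
        with pytest.raises(ValueError):
            compute_estimates(2.0, 2.0, p, "A", rng=None)

    def test_probability_matching_rate(self):
        p = BCIParams(0.5, 2, 2, 0.6, 0.6, strategy="probability_matching")
        rng = np.random.default_rng(1)
        x_a = np.full(20000, 3.0)
        x_v = np.full(20000, 1.0)  # fused and segregated estimates differ
        e = compute_estimates(x_a, x_v, p, "A", rng=rng)
        frac_fused = np.mean(np.isclose(e.n_final, e.n_fused))
        assert frac_fused == pytest.approx(float(e.post_common[0]), abs=0.02)


class TestButtonRule:
    @pytest.mark.parametrize(
        "value,button",
        [(-3.0, 1), (1.49, 1), (1.5, 2), (2.49, 2), (3.5, 4), (9.0, 4)],
    )
    def test_nearest_button(self, value, button):
        assert nearest_button(value) == button


class TestConditionDistribution:
    def test_noise_free_congruent(self):
        p = BCIParams(0.0, 2, 1e6, 0.01, 0.01)
        cd = predict_condition_distribution(
            p, (2, 2, "A"), 2000, np.random.default_rng(0)
        )
        assert cd.probs == pytest.approx([0, 1, 0, 0], abs=1e-9)

    def test_normalization_and_determinism(self, rng):
        p = BCIParams(0.42, 2.26, 2.34, 0.53, 1.11)
        cd1 = predict_condition_distribution(p, (1, 4, "V"), 3000,
                                             np.random.default_rng(5))
        cd2 = predict_condition_distribution(p, (1, 4, "V"), 3000,
                                             np.random.default_rng(5))
        assert cd1.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(cd1.probs, cd2.probs)

    def test_matches_2d_quadrature_oracle(self):
        """Monte-Carlo marginal vs dense quadrature over (x_A, x_V)."""
        p = BCIParams(0.5, 2, 2, 0.5, 1)
        cond = (2, 1, "V")  # 2 beeps, 1 flash, visual report
        gx = np.linspace(2 - 6 * 0.5, 2 + 6 * 0.5, 601)
        gy = np.linspace(1 - 6 * 1.0, 1 + 6 * 1.0, 601)
        XA, XV = np.meshgrid(gx, gy, indexing="ij")
        w = stats.norm.pdf(XA, 2, 0.5) * stats.norm.pdf(XV, 1, 1.0)
        est = compute_estimates(XA.ravel(), XV.ravel(), p, "V")
        b = bci_core.nearest_button(est.n_final)
        oracle = np.array(
            [np.sum(w.ravel() * (b == k)) for k in range(1, 5)]
        )
        oracle /= oracle.sum()
        cd = predict_condition_distribution(
            p, cond, 500_000, np.random.default_rng(7)
        )
        assert cd.probs == pytest.approx(oracle, abs=0.01)


class TestSimulateTrials:
    def test_noiseless_segregation_reports_truth(self, full_design):
        p = BCIParams(0.0, 2, 1e6, 1e-4, 1e-4)
        out = simulate_trials(p, full_design, np.random.default_rng(0))
        truth = np.where(out["task"] == "A", out["n_aud"], out["n_vis"])
        assert np.array_equal(out["response"].to_numpy(), truth)

    def test_histogram_matches_condition_distribution(self):
        """Self-consistency: simulated responses vs the predicted marginal."""
        p = BCIParams(0.42, 2.26, 2.34, 0.53, 1.11)
        cond = (3, 1, "A")
        design = pd.DataFrame(
            {"task": "A", "n_aud": 3, "n_vis": 1}, index=range(10_000)
        )
        out = simulate_trials(p, design, np.random.default_rng(3))
        emp = np.bincount(out["response"], minlength=5)[1:] / len(out)
        cd = predict_condition_distribution(
            p, cond, 200_000, np.random.default_rng(4)
        )
        assert np.abs(emp - cd.probs).sum() / 2 < 0.02  # total variation

    def test_forced_fusion_biases_visual_report_toward_beeps(self):
        p = BCIParams(1.0, 2.5, 3.0, 0.1, 1.5)
        design = pd.DataFrame(
            {"task": "V", "n_aud": 4, "n_vis": 1}, index=range(2000)
        )
        out = simulate_trials(p, design, np.random.default_rng(6))
        assert out["response"].mean() > 2.0  # pulled far above the true flash count


class TestTrialTableIO:
    def test_roundtrip_and_validation(self, tmp_path, sim_trials):
        path = tmp_path / "trials.csv"
        bci_core.write_trial_table(sim_trials, path)
        back = bci_core.read_trial_table(path)
        pd.testing.assert_frame_equal(
            back[bci_core.TRIAL_COLUMNS], sim_trials[bci_core.TRIAL_COLUMNS]
        )
        bad = sim_trials.copy()
        bad.loc[bad.index[0], "response"] = 9
        bci_core.write_trial_table(bad, path)
        with pytest.raises(ValueError):
            bci_core.read_trial_table(path)


@settings(max_examples=25, deadline=None)
@given(
    pc=st.floats(0.01, 0.99),
    mu=st.floats(1.0, 4.0),
    sp=st.floats(0.5, 4.0),
    sa=st.floats(0.3, 2.0),
    sv=st.floats(0.3, 2.0),
    xa=st.floats(-1.0, 6.0),
    xv=st.floats(-1.0, 6.0),
)
def test_posterior_properties(pc, mu, sp, sa, sv, xa, xv):
    """Posterior stays in [0,1] and complements the independent-cause term."""
    p = BCIParams(pc, mu, sp, sa, sv)
    q = posterior_common(xa, xv, p)
    assert 0.0 <= q <= 1.0
    # flipping the prior odds flips the posterior odds symmetrically
    q_flip = posterior_common(xa, xv, p.with_(p_common=1 - pc))
    odds = q / (1 - q) if q < 1 else np.inf
    prior_odds = pc / (1 - pc)
    lr = odds / prior_odds
    odds_flip = q_flip / (1 - q_flip)
    assert odds_flip * prior_odds == pytest.approx(lr, rel=1e-6)
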
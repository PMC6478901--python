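"""Time-frequency transform, decile sort-and-refit, phase models, history."""

import numpy as np
import pandas as pd
import pytest

from flashbeep import bci_core, model_fit, prestim_osc, stats_core, synthetic_data
from flashbeep.bci_core import BCIParams
from flashbeep.model_fit import SingleParamRefitter
from flashbeep.prestim_osc import (
    TFSeries,
    align_phase_profiles,
    decile_assign,
    decile_profile,
    history_labels,
    sinusoidal_phase_model,
    tf_transform,
)

GEN = BCIParams(0.42, 2.26, 2.34, 0.53, 1.11)


class TestTfTransform:
    def test_pure_10hz_oscillation(self):
        """Power peaks on the 10 Hz row and phase advances at 2*pi*10*dt."""
        sf = 200.0
        t = np.arange(-1.2, 0.6, 1 / sf)
        sig = np.cos(2 * np.pi * 10 * t)
        epochs = np.tile(sig, (2, 3, 1))
        tf = tf_transform(epochs, sf, epoch_tmin=-1.2,
                          freqs=np.arange(6.0, 31.0, 2.0))
        assert tf.freqs[np.argmax(tf.power[0].mean(axis=1))] == 10.0
        row = list(tf.freqs).index(10.0)
        steps = np.angle(np.exp(1j * np.diff(tf.phase[0, row])))
        dt = np.diff(tf.times)[0]
        assert np.allclose(steps, 2 * np.pi * 10 * dt, atol=0.05)

    def test_zero_signal_zero_power(self):
        tf = tf_transform(np.zeros((1, 2, 500)), 200.0, epoch_tmin=-1.5,
                          freqs=np.array([10.0]))
        assert np.allclose(tf.power, 0.0)

    def test_amplitude_doubling_quadruples_power(self):
        sf = 200.0
        t = np.arange(-1.2, 0.6, 1 / sf)
        sig = np.cos(2 * np.pi * 10 * t)
        tf1 = tf_transform(sig[None, None, :], sf, -1.2, freqs=np.array([10.0]))
        tf2 = tf_transform(2 * sig[None, None, :], sf, -1.2,
                           freqs=np.array([10.0]))
        assert np.allclose(tf2.power, 4 * tf1.power, rtol=1e-9)

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            tf_transform(np.zeros((1, 1, 40)), 200.0, -0.1,
                         freqs=np.array([6.0]))


@pytest.fixture(scope="module")
def participant():
    """One simulated participant with an alpha-power-linked causal prior."""
    rng = np.random.default_rng(77)
    design = synthetic_data.make_design(synthetic_data.ExperimentDesign(), 1, rng)
    spec = synthetic_data.OscillationSpec(b_alpha_power=-1.2)
    trials, extras = synthetic_data.generate_behavior(design, GEN, spec, rng)
    refitter = SingleParamRefitter(GEN, "p_common", np.random.default_rng(78))
    return trials, extras, refitter


class TestDecileMachinery:
    def test_membership_is_balanced_partition(self, participant):
        trials, extras, _ = participant
        codes = prestim_osc.condition_codes(trials)
        member = decile_assign(extras["alpha_power"].to_numpy(), codes)
        assert member.size == len(trials)
        sizes = np.bincount(member, minlength=10)
        assert sizes.sum() == len(trials)
        # near-equal within each condition
        for c in np.unique(codes):
            s = np.bincount(member[codes == c], minlength=10)
            assert s.max() - s.min() <= 1

    def test_sorting_is_within_condition(self, participant):
        trials, extras, _ = participant
        codes = prestim_osc.condition_codes(trials)
        v = extras["alpha_power"].to_numpy()
        member = decile_assign(v, codes)
        for c in np.unique(codes)[:5]:
            m = codes == c
            for d in range(9):
                lo, hi = v[m][member[m] == d], v[m][member[m] == d + 1]
                if lo.size and hi.size:
                    assert lo.max() <= hi.min()

    def test_profile_recovers_negative_alpha_linkage(self, participant):
        trials, extras, refitter = participant
        prof = decile_profile(
            extras["alpha_power"].to_numpy(), trials, refitter
        )
        r = np.corrcoef(prof.metric_mean, prof.param)[0, 1]
        assert r < -0.7

    def test_pooled_refit_matches_full_data(self, participant):
        trials, extras, refitter = participant
        full = refitter.refit(trials)
        prof = decile_profile(extras["alpha_power"].to_numpy(), trials, refitter)
        assert abs(np.mean(prof.param) - full) < 0.08


class TestSinusoidalModel:
    def test_constant_profile_nonsignificant(self):
        phases = np.linspace(-np.pi, np.pi, 10, endpoint=False)
        fit = sinusoidal_phase_model(np.full(10, 0.5), phases)
        assert abs(fit.beta_sin) < 1e-9 and abs(fit.beta_cos) < 1e-9
        assert fit.p_value > 0.9

    def test_recovery_of_injected_sinusoid(self):
        rng = np.random.default_rng(0)
        phases = np.linspace(-np.pi, np.pi, 10, endpoint=False)
        y = 0.5 + 0.2 * np.sin(phases - 0.3 * np.pi) + 0.01 * rng.standard_normal(10)
        fit = sinusoidal_phase_model(y, phases)
        assert fit.amplitude == pytest.approx(0.2, rel=0.10)
        # y = A sin(phi - d) = A cos(d) sin(phi) - A sin(d) cos(phi)
        expected_angle = np.angle(-0.2 * np.sin(0.3 * np.pi)
                                  + 1j * 0.2 * np.cos(0.3 * np.pi))
        assert abs(stats_core.circ_dist(fit.phase_angle, expected_angle)) < 0.1 * np.pi

    def test_constrained_variant_df_2_107(self):
        """10 deciles x 11 time points at 50 Hz in [-280, -80] ms -> df (2,107)."""
        rng = np.random.default_rng(1)
        times = np.arange(-0.28, -0.079, 0.02)
        assert times.size == 11
        phi = rng.uniform(-np.pi, np.pi, (10, 11))
        y = 0.4 + 0.1 * np.sin(2 * np.pi * 10 * (times - times[0])[None, :] - phi)
        fit = sinusoidal_phase_model(
            y, phi, variant="constrained_10hz", times=times
        )
        assert fit.df == (2, 107)
        assert fit.p_value < 1e-6

    def test_rank_deficient_regressors_rejected(self):
        with pytest.raises(ValueError):
            sinusoidal_phase_model(np.ones(10), np.zeros(10))


class TestAlignment:
    def test_identity_when_already_aligned(self):
        prof = np.tile(np.sin(np.linspace(0, 2 * np.pi, 10))[None, :, None],
                       (5, 1, 3))
        pred, obs, shifts = align_phase_profiles(prof, prof, 1)
        assert np.all(shifts == 0)
        assert np.allclose(pred, prof)

    def test_shift_by_full_cycle_is_identity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((1, 10, 2))
        assert np.allclose(np.roll(x, 10, axis=1), x)

    def test_random_offsets_realigned(self):
        """Known random circular offsets of a common sinusoid realign to
        nearly the individual amplitude."""
        rng = np.random.default_rng(3)
        base = 0.5 + 0.2 * np.sin(np.linspace(0, 2 * np.pi, 10, endpoint=False))
        profs = np.stack(
            [np.roll(base, rng.integers(0, 10))[:, None] * np.ones((10, 4))
             for _ in range(12)]
        )
        pred, obs, _ = align_phase_profiles(profs, profs, reference_time_index=0)
        group = pred.mean(axis=0)[:, 0]
        assert np.ptp(group) >= 0.9 * np.ptp(base)


class TestHistory:
    def test_labels_respect_run_boundaries(self):
        trials = pd.DataFrame(
            {
                "run": [1, 1, 1, 2, 2],
                "trial": [0, 1, 2, 0, 1],
                "n_aud": [1, 4, 2, 1, 3],
                "n_vis": [1, 1, 2, 1, 1],
            }
        )
        lab = history_labels(trials, 1)
        assert pd.isna(lab.iloc[0]) and pd.isna(lab.iloc[3])
        assert lab.iloc[1] == "small"  # previous (1,1)
        assert lab.iloc[2] == "large"  # previous (4,1)

    def test_identical_class_sets_zero_difference(self, participant):
        trials, _, refitter = participant
        labels = history_labels(trials, 1)
        sub = trials.loc[labels == "small"]
        a = refitter.refit_counts(model_fit.counts_by_condition(sub))
        b = refitter.refit_counts(model_fit.counts_by_condition(sub))
        assert a == b

    def test_history_linked_prior_recovered_at_order_one(self):
        """Generator boosts the prior after small-disparity trials; the
        order-1 contrast recovers it and decays over orders."""
        rng = np.random.default_rng(5)
        spec = synthetic_data.OscillationSpec(b_history=0.8, history_decay=0.4)
        profiles = []
        for pid in range(6):
            design = synthetic_data.make_design(
                synthetic_data.ExperimentDesign(), pid, rng
            )
            trials, _ = synthetic_data.generate_behavior(design, GEN, spec, rng)
            refitter = SingleParamRefitter(
                GEN, "p_common", np.random.default_rng(50 + pid)
            )
            profiles.append(prestim_osc.history_refits(trials, refitter))
        res = prestim_osc.history_analysis(np.stack(profiles))
        diffs = np.stack(profiles)[:, 0, :] - np.stack(profiles)[:, 1, :]
        assert res["posthoc"][0]["p"] < 0.05
        assert diffs[:, 0].mean() > diffs[:, 4].mean()
        assert res["anova"]["factor_a"].p_value < 0.05


def test_moderation_identical_classes_zero_contrast(participant):
    """With power surfaces identical across history classes the mediation
    contrast is exactly zero wherever class counts match."""
    trials, extras, refitter = participant
    labels = history_labels(trials, 1)
    ok = labels.isin(["small", "large"]).to_numpy()
    n = ok.sum()
    power = np.ones((len(trials), 2, 2))
    tf = TFSeries(power, np.zeros_like(power), np.array([8.0, 10.0]),
                  np.array([-0.3, -0.2]))
    small = (labels == "small").to_numpy()
    large = (labels == "large").to_numpy()
    diff = tf.power[small].mean(axis=0) - tf.power[large].mean(axis=0)
    assert np.allclose(diff, 0.0)
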
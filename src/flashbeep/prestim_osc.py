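"""Prestimulus oscillations and the causal prior.

Single-trial spectral power and phase are extracted with complex Morlet
wavelets (6-80 Hz in 2 Hz steps, cycles increasing linearly from 5 to 13),
averaged over an occipital channel set and downsampled to 50 Hz on a window
from -0.5 to +0.1 s around stimulus onset.  Trials are sorted into 10 deciles
of power (or phase) separately within each of the 32 conditions, the causal
prior p_common (or the visual noise sigma_V) is refitted per decile with the
remaining observer parameters fixed, and the decile profile is correlated
with the oscillatory metric: Pearson r for power, circular-linear correlation
with a within-participant permutation percentile for phase, both followed by
sign-flip cluster tests over the time-frequency grid.  Sinusoidal models of
the phase-decile profile, circular alignment of participants' phase profiles,
the stimulus-history analysis of the causal prior, and the alpha-power
mediation/moderation analyses complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import stats_core
from .model_fit import SingleParamRefitter, counts_by_condition
from .stats_core import DEFAULT_N_PERM, circ_mean

OCCIPITAL_CHANNELS = ("O1", "O2", "Oz", "PO3", "POz", "PO4")

BANDS = {"alpha": (8.0, 12.0), "beta": (14.0, 28.0), "gamma": (30.0, 80.0)}

DEFAULT_FREQS = np.arange(6.0, 81.0, 2.0)
N_DECILES = 10


@dataclass
class TFSeries:
    """Single-trial power and phase over a (frequency, time) grid.

    power: (n_trials, n_freqs, n_times), amplitude-squared units, >= 0.
    phase: same shape, radians wrapped to (-pi, pi].
    """

    power: np.ndarray
    phase: np.ndarray
    freqs: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        if self.power.shape != self.phase.shape:
            raise ValueError("power and phase shapes differ")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def band_mask(self, band: str | tuple) -> np.ndarray:
        lo, hi = BANDS[band] if isinstance(band, str) else band
        return (self.freqs >= lo) & (self.freqs <= hi)

    def select(self, band=None, tmin=None, tmax=None) -> "TFSeries":
        fm = np.ones(self.freqs.size, bool) if band is None else self.band_mask(band)
        tm = np.ones(self.times.size, bool)
        if tmin is not None:
            tm &= self.times >= tmin - 1e-9
        if tmax is not None:
            tm &= self.times <= tmax + 1e-9
        return TFSeries(
            self.power[:, fm][:, :, tm],
            self.phase[:, fm][:, :, tm],
            self.freqs[fm],
            self.times[tm],
        )


def morlet_cycles(freqs: np.ndarray, lo: float = 5.0, hi: float = 13.0):
    """Cycles increasing linearly from ``lo`` to ``hi`` across frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 1:
        return np.array([lo])
    return lo + (hi - lo) * (freqs - freqs[0]) / (freqs[-1] - freqs[0])


def tf_transform(
    epochs: np.ndarray,
    sfreq: float,
    epoch_tmin: float,
    freqs: np.ndarray = DEFAULT_FREQS,
    out_sfreq: float = 50.0,
    crop: tuple[float, float] = (-0.5, 0.1),
    channel_average: bool = True,
) -> TFSeries:
    """Complex Morlet transform of (trials x channels x samples) epochs.

    Power is averaged across the supplied channels; the per-trial phase is the
    circular mean of the per-channel phases (mean of unit phasors).  The
    time-frequency representation is downsampled to ``out_sfreq`` and cropped
    to the analysis window.  Epochs must extend beyond the window by at least
    half the wavelet support at the lowest frequency.
    """
    from mne.time_frequency import tfr_array_morlet

    epochs = np.asarray(epochs, dtype=float)
    n_trials, n_chan, n_samp = epochs.shape
    freqs = np.asarray(freqs, dtype=float)
    cycles = morlet_cycles(freqs)
    support = cycles[0] / freqs[0]
    if n_samp / sfreq < support:
        raise ValueError("epoch shorter than the wavelet support at the lowest frequency")
    tfr = tfr_array_morlet(
        epochs, sfreq=sfreq, freqs=freqs, n_cycles=cycles, output="complex",
        zero_mean=True,
    )
    # mne >= 1.x returns (n_trials, n_chan, [n_tapers,] n_freqs, n_times)
    if tfr.ndim == 5:
        tfr = tfr[:, :, 0]
    times = epoch_tmin + np.arange(n_samp) / sfreq
    step = max(1, int(round(sfreq / out_sfreq)))
    keep = np.arange(0, n_samp, step)
    keep = keep[(times[keep] >= crop[0] - 1e-9) & (times[keep] <= crop[1] + 1e-9)]
    tfr = tfr[..., keep]
    power_ch = np.abs(tfr) ** 2
    if channel_average:
        power = power_ch.mean(axis=1)
        unit = tfr / np.maximum(np.abs(tfr), 1e-300)
        phase = np.angle(unit.mean(axis=1))
    else:
        power, phase = power_ch, np.angle(tfr)
    return TFSeries(power, phase, freqs, times[keep])


# ---------------------------------------------------------------------------
# Decile sort-and-refit
# ---------------------------------------------------------------------------


@dataclass
class DecileProfile:
    membership: np.ndarray          # decile index 0..9 per trial
    metric_mean: np.ndarray         # (10,) mean power or circular-mean phase
    param: np.ndarray               # (10,) refitted parameter per decile


def decile_assign(
    values: np.ndarray, condition_codes: np.ndarray, n_deciles: int = N_DECILES
) -> np.ndarray:
    """Decile membership, sorting within each condition before pooling.

    Rank-based: within every condition the sorted trials are split into
    ``n_deciles`` near-equal bins (sizes differ by at most 1).  For phase
    values in (-pi, pi] this realises circular deciles whose boundaries start
    at -pi.
    """
    values = np.asarray(values, dtype=float)
    out = np.empty(values.size, dtype=int)
    for c in np.unique(condition_codes):
        idx = np.flatnonzero(condition_codes == c)
        order = idx[np.argsort(values[idx], kind="stable")]
        ranks = np.arange(order.size)
        out[order] = (ranks * n_deciles) // order.size
    return out


def condition_codes(trials: pd.DataFrame) -> np.ndarray:
    """Integer code of the 32-condition cell per trial."""
    task_code = (trials["task"] == "V").to_numpy(int)
    return (
        task_code * 16
        + (trials["n_aud"].to_numpy(int) - 1) * 4
        + (trials["n_vis"].to_numpy(int) - 1)
    )


def decile_profile(
    metric: np.ndarray,
    trials: pd.DataFrame,
    refitter: SingleParamRefitter,
    circular: bool = False,
    n_deciles: int = N_DECILES,
) -> DecileProfile:
    """Sort trials into metric deciles (within condition) and refit per decile."""
    codes = condition_codes(trials)
    member = decile_assign(metric, codes, n_deciles)
    if np.unique(member).size < n_deciles:
        raise ValueError("fewer than the requested number of occupied deciles")
    responses = trials["response"].to_numpy(int) - 1
    counts = np.zeros((n_deciles, 32, 4))
    np.add.at(counts, (member, codes, responses), 1.0)
    metric_mean = np.empty(n_deciles)
    param = np.empty(n_deciles)
    for d in range(n_deciles):
        m = member == d
        metric_mean[d] = circ_mean(metric[m]) if circular else metric[m].mean()
        param[d] = refitter.refit_counts(counts[d])
    return DecileProfile(member, metric_mean, param)


def power_correlation_map(
    tf: TFSeries,
    trials: pd.DataFrame,
    refitter: SingleParamRefitter,
    n_deciles: int = N_DECILES,
) -> np.ndarray:
    """(n_freqs, n_times) Pearson r between decile power and refitted
    parameter, for one participant."""
    nf, nt = tf.power.shape[1:]
    out = np.empty((nf, nt))
    for i in range(nf):
        for j in range(nt):
            prof = decile_profile(tf.power[:, i, j], trials, refitter,
                                  n_deciles=n_deciles)
            if np.ptp(prof.metric_mean) == 0 or np.ptp(prof.param) == 0:
                out[i, j] = np.nan  # degenerate: identical deciles, flagged
            else:
                out[i, j] = np.corrcoef(prof.metric_mean, prof.param)[0, 1]
    return out


def phase_percentile_map(
    tf: TFSeries,
    trials: pd.DataFrame,
    refitter: SingleParamRefitter,
    n_shuffle: int = 1000,
    rng: np.random.Generator | None = None,
    n_deciles: int = N_DECILES,
) -> np.ndarray:
    """(n_freqs, n_times) percentile of the observed circular-linear
    correlation within the participant's own shuffle null.

    The decile <-> parameter assignment is shuffled ``n_shuffle`` times; the
    percentile of the true correlation in that null distribution is an
    unbiased per-participant statistic (50% under independence).
    """
    rng = np.random.default_rng() if rng is None else rng
    nf, nt = tf.phase.shape[1:]
    out = np.empty((nf, nt))
    for i in range(nf):
        for j in range(nt):
            prof = decile_profile(tf.phase[:, i, j], trials, refitter,
                                  circular=True, n_deciles=n_deciles)
            if np.ptp(prof.param) == 0:
                out[i, j] = 50.0
                continue
            obs = stats_core.circular_linear_correlation(
                prof.metric_mean, prof.param
            )
            null = np.empty(n_shuffle)
            for s in range(n_shuffle):
                null[s] = stats_core.circular_linear_correlation(
                    rng.permutation(prof.metric_mean), prof.param
                )
            out[i, j] = 100.0 * np.mean(null < obs)
    return out


def power_correlation_test(
    r_maps: np.ndarray,
    threshold: float = 2.0,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
) -> stats_core.ClusterTestResult:
    """Two-sided group cluster test on Fisher-z decile-power correlations."""
    z = stats_core.fisher_z(np.nan_to_num(np.asarray(r_maps)))
    return stats_core.cluster_randomization_test(
        z, threshold=threshold, n_perm=n_perm, tail="two-sided", rng=rng
    )


def phase_percentile_test(
    percentile_maps: np.ndarray,
    threshold: float = 2.0,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
) -> stats_core.ClusterTestResult:
    """One-sided group test that mean percentile exceeds 50%."""
    dev = np.asarray(percentile_maps, dtype=float) - 50.0
    return stats_core.cluster_randomization_test(
        dev, threshold=threshold, n_perm=n_perm, tail="greater", rng=rng
    )


# ---------------------------------------------------------------------------
# Sinusoidal models of the phase-decile profile
# ---------------------------------------------------------------------------


@dataclass
class SinusoidalFit:
    beta_sin: float
    beta_cos: float
    constant: float
    f_statistic: float
    df: tuple[float, float]
    p_value: float
    variant: str
    predicted: np.ndarray = field(default=None, repr=False)

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.beta_sin, self.beta_cos))

    @property
    def phase_angle(self) -> float:
        """angle(beta_cos + i beta_sin), radians."""
        return float(np.angle(self.beta_cos + 1j * self.beta_sin))


def _sin_fit(y: np.ndarray, arg: np.ndarray, variant: str) -> SinusoidalFit:
    X = np.column_stack([np.sin(arg), np.cos(arg), np.ones(arg.size)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient sinusoidal regressors")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ beta
    rss = np.sum((y - pred) ** 2)
    rss0 = np.sum((y - y.mean()) ** 2)
    df1, df2 = 2, y.size - 3
    F = ((rss0 - rss) / df1) / (rss / df2) if rss > 0 else np.inf
    p = stats.f.sf(F, df1, df2)
    return SinusoidalFit(
        float(beta[0]), float(beta[1]), float(beta[2]), float(F), (df1, df2),
        float(p), variant, predicted=pred,
    )


def sinusoidal_phase_model(
    p_common_dec: np.ndarray,
    phase_dec: np.ndarray,
    variant: str = "time_specific",
    times: np.ndarray | None = None,
    carrier_hz: float = 10.0,
) -> SinusoidalFit:
    """Sinusoidal regression of the causal prior on decile phase.

    time_specific: profiles are 1-D over deciles for one time point and the
    regressors are sin/cos of the decile-mean phase.  constrained_10hz:
    profiles are (n_deciles, n_times); one single sine/cosine pair at the
    carrier frequency predicts all deciles and time points from the argument
    2*pi*F*t - phase(dec, t), so the modulation is constrained to evolve at
    the carrier rhythm over time (t = 0 at the first analysed sample; the
    origin only rotates the fitted phase angle).
    """
    y = np.asarray(p_common_dec, dtype=float)
    phi = np.asarray(phase_dec, dtype=float)
    if variant == "time_specific":
        return _sin_fit(y.ravel(), phi.ravel(), variant)
    if variant != "constrained_10hz":
        raise ValueError(f"unknown variant {variant!r}")
    if times is None or y.ndim != 2:
        raise ValueError("constrained variant needs (deciles, times) profiles and times")
    t_rel = np.asarray(times, float) - float(np.asarray(times).ravel()[0])
    arg = 2 * np.pi * carrier_hz * t_rel[None, :] - phi
    fit = _sin_fit(y.ravel(), arg.ravel(), variant)
    fit.predicted = fit.predicted.reshape(y.shape)
    return fit


def align_phase_profiles(
    predicted: np.ndarray,
    observed: np.ndarray,
    reference_time_index: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Circularly shift each participant's decile axis to the group peak.

    ``predicted``/``observed``: (n_subj, n_deciles, n_times).  The peak decile
    of each participant's predicted profile at the reference time is aligned
    with the group peak decile there; the identical circular shift is applied
    to the observed profiles at all times.  Returns (aligned predicted,
    aligned observed, shifts).  Non-unique peaks take the first maximum.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    n_subj, n_dec, _ = pred.shape
    group_peak = int(np.argmax(pred[:, :, reference_time_index].mean(axis=0)))
    shifts = np.empty(n_subj, dtype=int)
    pred_out = np.empty_like(pred)
    obs_out = np.empty_like(obs)
    for i in range(n_subj):
        peak_i = int(np.argmax(pred[i, :, reference_time_index]))
        shifts[i] = (group_peak - peak_i) % n_dec
        pred_out[i] = np.roll(pred[i], shifts[i], axis=0)
        obs_out[i] = np.roll(obs[i], shifts[i], axis=0)
    return pred_out, obs_out, shifts


# ---------------------------------------------------------------------------
# Stimulus history and moderation
# ---------------------------------------------------------------------------


def history_labels(trials: pd.DataFrame, order: int) -> pd.Series:
    """Previous-trial disparity class ('small'/'large') at a given order.

    History is computed within runs only; the first ``order`` trials of each
    run have no predecessor and receive NaN.
    """
    df = trials.sort_values(["run", "trial"]) if "trial" in trials else trials
    disp = np.where(
        np.abs(df["n_aud"] - df["n_vis"]) <= 1, "small", "large"
    )
    prev = pd.Series(disp, index=df.index).groupby(df["run"]).shift(order)
    return prev.reindex(trials.index)


def history_refits(
    trials: pd.DataFrame,
    refitter: SingleParamRefitter,
    orders=(1, 2, 3, 4, 5),
) -> np.ndarray:
    """(2, n_orders) refitted p_common for previous small/large disparity."""
    out = np.empty((2, len(orders)))
    for j, order in enumerate(orders):
        labels = history_labels(trials, order)
        for i, cls in enumerate(("small", "large")):
            sub = trials.loc[labels == cls]
            if len(sub) < 32:
                raise ValueError(
                    f"insufficient trials in history class {cls!r} order {order}"
                )
            out[i, j] = refitter.refit_counts(counts_by_condition(sub))
    return out


def history_analysis(profiles: np.ndarray) -> dict:
    """Group inference on (n_subj, 2, n_orders) history-conditioned priors.

    Runs the 2 x k repeated-measures ANOVA with Greenhouse-Geisser correction
    plus per-order two-sided paired t tests (small minus large disparity).
    """
    y = np.asarray(profiles, dtype=float)
    anova = stats_core.rm_anova_2xk(y)
    n_orders = y.shape[2]
    posthoc = []
    for j in range(n_orders):
        t, p = stats.ttest_rel(y[:, 0, j], y[:, 1, j])
        d = (y[:, 0, j] - y[:, 1, j]).mean() / (y[:, 0, j] - y[:, 1, j]).std(ddof=1)
        posthoc.append({"order": j + 1, "t": float(t), "p": float(p),
                        "cohens_d": float(d)})
    return {"anova": anova, "posthoc": posthoc, "profiles": y}


def moderation_analysis(
    tfs: list[TFSeries],
    trials_list: list[pd.DataFrame],
    refitters: list[SingleParamRefitter],
    threshold: float = 2.0,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
    n_deciles: int = N_DECILES,
) -> dict:
    """Mediation and moderation of the alpha-power effect by stimulus history.

    (i) mediation check: two-sided cluster test of the power difference
    between previous small- vs large-disparity trials; (ii) decile power
    correlations computed separately per history class; (iii) moderation:
    two-sided cluster test on the Fisher-z correlation difference.
    """
    rng = np.random.default_rng() if rng is None else rng
    n_subj = len(tfs)
    shape = tfs[0].power.shape[1:]
    power_diff = np.empty((n_subj,) + shape)
    r_small = np.empty((n_subj,) + shape)
    r_large = np.empty((n_subj,) + shape)
    for s in range(n_subj):
        labels = history_labels(trials_list[s], order=1)
        for cls, dest in (("small", r_small), ("large", r_large)):
            mask = (labels == cls).to_numpy()
            sub_tf = TFSeries(
                tfs[s].power[mask], tfs[s].phase[mask], tfs[s].freqs, tfs[s].times
            )
            dest[s] = power_correlation_map(
                sub_tf, trials_list[s].loc[mask].reset_index(drop=True),
                refitters[s], n_deciles=n_deciles,
            )
        small = (labels == "small").to_numpy()
        large = (labels == "large").to_numpy()
        power_diff[s] = tfs[s].power[small].mean(axis=0) - tfs[s].power[large].mean(
            axis=0
        )
    mediation = stats_core.cluster_randomization_test(
        power_diff, threshold=threshold, n_perm=n_perm, tail="two-sided", rng=rng
    )
    z_diff = stats_core.fisher_z(np.nan_to_num(r_small)) - stats_core.fisher_z(
        np.nan_to_num(r_large)
    )
    moderation = stats_core.cluster_randomization_test(
        z_diff, threshold=threshold, n_perm=n_perm, tail="two-sided", rng=rng
    )
    return {
        "mediation": mediation,
        "moderation": moderation,
        "r_small": r_small,
        "r_large": r_large,
        "power_diff": power_diff,
    }
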
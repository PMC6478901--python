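"""Synthetic behavioural, neural-pattern and oscillatory data.

The generator reproduces the statistical structure every analysis stage
assumes: the 4 (beeps) x 4 (flashes) x 2 (report modality) factorial design
with 10 trials per condition per run and 8 audiovisual runs (4 auditory-, 4
visual-report) per participant; responses sampled from the causal-inference
generative process, optionally with a trial-wise effective causal prior
driven by prestimulus oscillatory state and stimulus history through a
logistic link; activity patterns that linearly encode selected internal
estimates with time-varying weights and Gaussian noise; and time-frequency
surfaces whose alpha/gamma amplitudes and alpha phase are exactly the values
that entered the link, on top of a 1/f background.

Everything is deterministic given the seed: one `numpy` Generator drives the
whole experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import special

from . import bci_core
from .bci_core import BCIParams
from .neural_decode import PatternSeries, _zscore_features
from .prestim_osc import TFSeries

#: group-level generating parameters (means and between-participant SDs)
#: for the causal-inference observer under model averaging.
GROUP_PARAM_MEANS = {
    "p_common": 0.42,
    "mu_p": 2.26,
    "sigma_p": 2.34,
    "sigma_a": 0.53,
    "sigma_v": 1.11,
}
GROUP_PARAM_SDS = {
    "p_common": 0.15,
    "mu_p": 0.5,
    "sigma_p": 0.7,
    "sigma_a": 0.12,
    "sigma_v": 0.4,
}


@dataclass
class ExperimentDesign:
    n_participants: int = 23
    n_av_runs: int = 8          # 4 auditory-report + 4 visual-report
    trials_per_condition_per_run: int = 10
    n_unisensory_runs: int = 2
    slot_onsets_s: tuple = (0.0, 0.0667, 0.133, 0.2)

    @property
    def trials_per_participant(self) -> int:
        return self.n_av_runs * 16 * self.trials_per_condition_per_run


@dataclass
class OscillationSpec:
    """Distributions of prestimulus state and its linkage to the causal prior.

    Trial-wise log alpha/gamma power are Gaussian; alpha phase is uniform.
    The effective causal prior is logistic in the standardised predictors:
    logit(p_eff) = logit(p_common) + b_alpha * z(log alpha) + b_gamma *
    z(log gamma) + b_phase * cos(phase - phase_ref) + history, where history
    adds b_history * decay**(order-1) * (+1 for a small-, -1 for a
    large-disparity predecessor) per order.  Coefficients are log-odds per SD.
    """

    alpha_log_power: tuple = (1.5, 0.4)   # mean, sd of log amplitude^2
    gamma_log_power: tuple = (0.0, 0.4)
    b_alpha_power: float = 0.0
    b_gamma_power: float = 0.0
    b_alpha_phase: float = 0.0
    phase_ref: float = 0.0
    b_history: float = 0.0
    history_decay: float = 0.5
    n_history_orders: int = 5
    link_freq_hz: float = 10.0
    link_time_s: float = -0.2

    def draw_state(self, n_trials: int, rng: np.random.Generator) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha_power": np.exp(
                    self.alpha_log_power[0]
                    + self.alpha_log_power[1] * rng.standard_normal(n_trials)
                ),
                "gamma_power": np.exp(
                    self.gamma_log_power[0]
                    + self.gamma_log_power[1] * rng.standard_normal(n_trials)
                ),
                "alpha_phase": rng.uniform(-np.pi, np.pi, n_trials),
            }
        )


@dataclass
class EncodingSpec:
    """Linear encoding of internal estimates in activity patterns.

    ``weights`` maps estimate name -> per-time-bin encoding weight (>= 0).
    Each encoded estimate gets a fixed random unit loading vector over
    features; run-level multiplicative gain jitter and i.i.d. Gaussian noise
    complete the pattern model.
    """

    weights: dict[str, np.ndarray]
    n_features: int = 64
    bin_times: np.ndarray = None
    noise_sd: float = 1.0
    run_gain_sd: float = 0.0

    def __post_init__(self):
        lens = {len(np.atleast_1d(w)) for w in self.weights.values()}
        if len(lens) != 1:
            raise ValueError("all weight vectors must share one length")
        (self.n_bins,) = lens
        if self.bin_times is None:
            self.bin_times = np.arange(self.n_bins) * 0.02
        for name, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            if np.any(w < 0):
                raise ValueError("encoding weights must be non-negative")
            self.weights[name] = w
        if not any(w.max() > 0 for w in self.weights.values()):
            raise ValueError("at least one time-bin must have a nonzero weight")


# ---------------------------------------------------------------------------
# Design and behaviour
# ---------------------------------------------------------------------------


def draw_participant_params(
    rng: np.random.Generator,
    n: int,
    strategy: str = "model_averaging",
) -> list[BCIParams]:
    """Observer parameters per participant, drawn around the group means."""
    out = []
    for _ in range(n):
        vals = {
            k: GROUP_PARAM_MEANS[k] + GROUP_PARAM_SDS[k] * rng.standard_normal()
            for k in GROUP_PARAM_MEANS
        }
        vals["p_common"] = float(np.clip(vals["p_common"], 0.05, 0.95))
        vals["mu_p"] = float(np.clip(vals["mu_p"], 1.0, 4.0))
        for k in ("sigma_p", "sigma_a", "sigma_v"):
            vals[k] = float(np.clip(vals[k], 0.2, None))
        out.append(BCIParams(strategy=strategy, **vals))
    return out


def make_design(
    design: ExperimentDesign,
    participant: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One participant's audiovisual design: randomized trial order per run."""
    rows = []
    for run in range(1, design.n_av_runs + 1):
        task = "A" if run % 2 == 1 else "V"
        cells = [
            (na, nv)
            for na in range(1, 5)
            for nv in range(1, 5)
            for _ in range(design.trials_per_condition_per_run)
        ]
        order = rng.permutation(len(cells))
        for t, k in enumerate(order):
            na, nv = cells[k]
            rows.append(
                {
                    "participant": participant,
                    "run": run,
                    "trial": t,
                    "task": task,
                    "n_aud": na,
                    "n_vis": nv,
                }
            )
    return pd.DataFrame(rows)


def _history_signal(design: pd.DataFrame, spec: OscillationSpec) -> np.ndarray:
    """Summed, geometrically decaying history drive (within runs only)."""
    disp_small = (np.abs(design["n_aud"] - design["n_vis"]) <= 1).astype(float)
    signed = 2.0 * disp_small - 1.0  # +1 small, -1 large
    signal = np.zeros(len(design))
    s = pd.Series(signed, index=design.index)
    for order in range(1, spec.n_history_orders + 1):
        prev = s.groupby(design["run"]).shift(order).fillna(0.0)
        signal += spec.history_decay ** (order - 1) * prev.to_numpy()
    return spec.b_history * signal


def effective_p_common(
    base_p_common: float,
    state: pd.DataFrame,
    design: pd.DataFrame,
    spec: OscillationSpec,
) -> np.ndarray:
    """Trial-wise causal prior through the logistic link; always in (0, 1)."""
    z_alpha = _standardize(np.log(state["alpha_power"].to_numpy()))
    z_gamma = _standardize(np.log(state["gamma_power"].to_numpy()))
    phase = state["alpha_phase"].to_numpy()
    logit = (
        special.logit(np.clip(base_p_common, 1e-6, 1 - 1e-6))
        + spec.b_alpha_power * z_alpha
        + spec.b_gamma_power * z_gamma
        + spec.b_alpha_phase * np.cos(phase - spec.phase_ref)
        + _history_signal(design, spec)
    )
    return special.expit(logit)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_behavior(
    design: pd.DataFrame,
    params: BCIParams,
    osc_spec: OscillationSpec | None = None,
    rng: np.random.Generator | None = None,
):
    """Simulate one participant's responses (plus per-trial state record).

    Returns (trials, extras): ``trials`` adds the response column to the
    design; ``extras`` records the oscillatory state, the effective causal
    prior and the internal estimates of every trial.
    """
    rng = np.random.default_rng() if rng is None else rng
    if osc_spec is None:
        p_eff = None
        state = None
    else:
        state = osc_spec.draw_state(len(design), rng)
        p_eff = effective_p_common(params.p_common, state, design, osc_spec)
    trials, est = bci_core.simulate_trials(
        params, design, rng, p_common_trial=p_eff, return_estimates=True
    )
    extras = pd.DataFrame(
        {
            "p_common_eff": p_eff if p_eff is not None else params.p_common,
            "n_fused": est.n_fused,
            "n_aud_seg": est.n_aud_seg,
            "n_vis_seg": est.n_vis_seg,
            "n_final": est.n_final,
            "post_common": est.post_common,
        }
    )
    if state is not None:
        extras = pd.concat([state.reset_index(drop=True), extras], axis=1)
    return trials, extras


def generate_group(
    design: ExperimentDesign | None = None,
    osc_spec: OscillationSpec | None = None,
    rng: np.random.Generator | None = None,
    params_list: list[BCIParams] | None = None,
):
    """Full synthetic experiment: (trials, extras, params) per participant."""
    design = design or ExperimentDesign()
    rng = np.random.default_rng() if rng is None else rng
    if params_list is None:
        params_list = draw_participant_params(rng, design.n_participants)
    out = {}
    for pid, params in enumerate(params_list, start=1):
        d = make_design(design, pid, rng)
        trials, extras = generate_behavior(d, params, osc_spec, rng)
        out[pid] = (trials, extras, params)
    return out


# ---------------------------------------------------------------------------
# Neural patterns and oscillations
# ---------------------------------------------------------------------------


def generate_patterns(
    trials: pd.DataFrame,
    estimates: pd.DataFrame,
    encoding: EncodingSpec,
    rng: np.random.Generator,
) -> PatternSeries:
    """Patterns linearly encoding internal estimates with Gaussian noise.

    pattern(trial, :, bin) = sum_e w_e(bin) * loading_e * value_e(trial) *
    run_gain + noise.  Features are z-scored per (feature, bin) as the
    decoding stage expects.
    """
    n_trials = len(trials)
    n_feat, n_bins = encoding.n_features, encoding.n_bins
    data = np.zeros((n_trials, n_feat, n_bins))
    for name, w in encoding.weights.items():
        loading = rng.standard_normal(n_feat)
        loading /= np.linalg.norm(loading)
        values = estimates[name].to_numpy(float)
        data += values[:, None, None] * loading[None, :, None] * w[None, None, :]
    if encoding.run_gain_sd > 0:
        runs = trials["run"].to_numpy()
        gains = {
            r: 1.0 + encoding.run_gain_sd * rng.standard_normal()
            for r in np.unique(runs)
        }
        data *= np.array([gains[r] for r in runs])[:, None, None]
    data += encoding.noise_sd * rng.standard_normal(data.shape)
    for b in range(n_bins):
        data[:, :, b] = _zscore_features(data[:, :, b])
    return PatternSeries(
        data, np.asarray(encoding.bin_times, float), trials.reset_index(drop=True)
    )


def generate_oscillations(
    state: pd.DataFrame,
    osc_spec: OscillationSpec,
    rng: np.random.Generator,
    freqs: np.ndarray = np.arange(6.0, 81.0, 2.0),
    times: np.ndarray = np.arange(-0.5, 0.101, 0.02),
    background_scale: float = 0.05,
) -> TFSeries:
    """Time-frequency surfaces consistent with the state used for behaviour.

    Alpha (8-12 Hz) power carries each trial's alpha amplitude, gamma
    (30-80 Hz) power its gamma amplitude, on a weak multiplicative-noise 1/f
    background; alpha phase advances at each row's frequency and equals the
    trial's linked phase at (link_freq, link_time).  Elsewhere phase is
    uniform noise.
    """
    freqs = np.asarray(freqs, float)
    times = np.asarray(times, float)
    n_trials = len(state)
    nf, nt = freqs.size, times.size
    power = (
        background_scale
        * (1.0 / freqs)[None, :, None]
        * np.exp(0.3 * rng.standard_normal((n_trials, nf, nt)))
    )
    alpha = state["alpha_power"].to_numpy(float)
    gamma = state["gamma_power"].to_numpy(float)
    phase = rng.uniform(-np.pi, np.pi, (n_trials, nf, nt))

    alpha_rows = (freqs >= 8) & (freqs <= 12)
    gamma_rows = (freqs >= 30) & (freqs <= 80)
    bump = np.exp(-0.5 * ((freqs[alpha_rows] - osc_spec.link_freq_hz) / 1.5) ** 2)
    power[:, alpha_rows, :] += (
        alpha[:, None, None] * bump[None, :, None]
    )
    gprof = np.exp(-0.5 * ((freqs[gamma_rows] - 50.0) / 15.0) ** 2)
    power[:, gamma_rows, :] += gamma[:, None, None] * gprof[None, :, None]

    phi0 = state["alpha_phase"].to_numpy(float)
    for i in np.flatnonzero(alpha_rows):
        evolution = 2 * np.pi * freqs[i] * (times - osc_spec.link_time_s)
        phase[:, i, :] = np.angle(
            np.exp(1j * (phi0[:, None] + evolution[None, :]))
        )
    return TFSeries(power, phase, freqs, times)


# ---------------------------------------------------------------------------
# ERP fixtures
# ---------------------------------------------------------------------------


def generate_erps(
    n_participants: int,
    n_times: int,
    rng: np.random.Generator,
    noise_sd: float = 0.3,
    superadditive: tuple[int, int, float] | None = None,
):
    """Channel-average ERPs for the audiovisual-interaction contrast.

    Generates smooth unisensory components A and V (shared across
    participants, plus participant noise) and AV = A + V (+ optional
    superadditive pulse over a sample window).  Returns (av, a, v) of shape
    (n_participants, n_times).
    """
    t = np.linspace(0, 1, n_times)
    base_a = np.sin(2 * np.pi * 3 * t) * np.exp(-3 * t)
    base_v = np.cos(2 * np.pi * 2 * t) * np.exp(-2 * t)
    a = base_a[None] + noise_sd * rng.standard_normal((n_participants, n_times))
    v = base_v[None] + noise_sd * rng.standard_normal((n_participants, n_times))
    av = (
        base_a[None]
        + base_v[None]
        + noise_sd * rng.standard_normal((n_participants, n_times))
    )
    if superadditive is not None:
        lo, hi, amp = superadditive
        av[:, lo:hi] += amp
    return av, a, v


def manifest(design: ExperimentDesign, osc_spec: OscillationSpec | None,
             seed: int) -> dict:
    """JSON-serialisable record of all generating parameters."""
    return {
        "seed": seed,
        "design": asdict(design),
        "oscillation_spec": None if osc_spec is None else {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(osc_spec).items()
        },
        "group_param_means": GROUP_PARAM_MEANS,
        "group_param_sds": GROUP_PARAM_SDS,
    }
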
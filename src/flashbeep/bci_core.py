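"""Bayesian Causal Inference (BCI) observer model for audiovisual numerosity.

The observer receives noisy internal measurements ``x_A`` and ``x_V`` of the
true number of auditory beeps and visual flashes (1-4 each) and must report the
count in one modality.  The generative model assumes that with prior
probability ``p_common`` both signals stem from a common cause, in which case a
single "true" count is drawn from a Gaussian numeric prior N(mu_p, sigma_p);
otherwise the auditory and visual counts are drawn independently from that
prior.  The observer inverts this model: it computes the posterior probability
of a common cause, a reliability-weighted fused estimate, unisensory
segregation estimates shrunk toward the prior, and combines them with one of
three decision strategies (model averaging, model selection, probability
matching).  Continuous estimates are mapped to the four response buttons by
proximity.

All operations are vectorised over trials/samples; scalars work too.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

Strategy = Literal["model_averaging", "model_selection", "probability_matching"]
Task = Literal["A", "V"]

#: Number of response buttons / maximum stimulus count.
N_BUTTONS = 4

#: Canonical ordering of the 32 experimental conditions:
#: (n_aud, n_vis, task) with task 'A' (auditory report) first.
CONDITIONS: list[tuple[int, int, str]] = [
    (na, nv, task) for task in ("A", "V") for na in range(1, 5) for nv in range(1, 5)
]

#: Required columns of a trial table (delimited text interface).
TRIAL_COLUMNS = ["participant", "run", "task", "n_aud", "n_vis", "response"]


@dataclass(frozen=True)
class BCIParams:
    """The five observer parameters plus decision strategy.

    p_common : prior probability of a common cause, in [0, 1].
    mu_p     : mean of the Gaussian numeric prior (stimulus-count units).
    sigma_p  : SD of the numeric prior (> 0).
    sigma_a  : auditory sensory noise SD (> 0).
    sigma_v  : visual sensory noise SD (> 0).

    Forced fusion is the special case ``p_common = 1``; full segregation is
    ``p_common = 0``.
    """

    p_common: float
    mu_p: float
    sigma_p: float
    sigma_a: float
    sigma_v: float
    strategy: Strategy = "model_averaging"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_common <= 1.0:
            raise ValueError(f"p_common must be in [0, 1], got {self.p_common}")
        for name in ("sigma_p", "sigma_a", "sigma_v"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.strategy not in (
            "model_averaging",
            "model_selection",
            "probability_matching",
        ):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    def with_(self, **kwargs) -> "BCIParams":
        return replace(self, **kwargs)


@dataclass
class EstimateSet:
    """Per-trial internal estimates of the observer (arrays or scalars)."""

    n_fused: np.ndarray
    n_aud_seg: np.ndarray
    n_vis_seg: np.ndarray
    n_final: np.ndarray
    post_common: np.ndarray


@dataclass
class ConditionDistribution:
    """Predicted 4-bin response probabilities for one condition."""

    condition: tuple[int, int, str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_BUTTONS,):
            raise ValueError("probs must be a 4-vector")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be non-negative and sum to 1")


# ---------------------------------------------------------------------------
# Posterior over causal structures and conditional estimates
# ---------------------------------------------------------------------------


def _log_lik_common(x_a, x_v, params: BCIParams):
    """log p(x_A, x_V | C=1): both measurements share one latent count.

    Closed form of the Gaussian integral
    int N(x_A; N, s_A) N(x_V; N, s_V) N(N; mu_p, s_P) dN.
    """
    va, vv, vp = params.sigma_a**2, params.sigma_v**2, params.sigma_p**2
    denom = va * vv + va * vp + vv * vp
    quad = (
        (x_a - x_v) ** 2 * vp
        + (x_a - params.mu_p) ** 2 * vv
        + (x_v - params.mu_p) ** 2 * va
    )
    return -0.5 * quad / denom - np.log(2.0 * np.pi * np.sqrt(denom))


def _log_lik_indep(x_a, x_v, params: BCIParams):
    """log p(x_A, x_V | C=2): independent latent counts per modality."""
    va = params.sigma_a**2 + params.sigma_p**2
    vv = params.sigma_v**2 + params.sigma_p**2
    quad = (x_a - params.mu_p) ** 2 / va + (x_v - params.mu_p) ** 2 / vv
    return -0.5 * quad - np.log(2.0 * np.pi * np.sqrt(va * vv))


def posterior_common(x_a, x_v, params: BCIParams):
    """Posterior probability of a common cause, p(C=1 | x_A, x_V)."""
    x_a = np.asarray(x_a, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    if not (np.all(np.isfinite(x_a)) and np.all(np.isfinite(x_v))):
        raise ValueError("sensory samples must be finite")
    if params.p_common == 1.0:
        return np.ones_like(x_a)[()] if x_a.ndim else 1.0
    if params.p_common == 0.0:
        return np.zeros_like(x_a)[()] if x_a.ndim else 0.0
    # Work with the log likelihood ratio for numerical stability.
    log_lr = _log_lik_common(x_a, x_v, params) - _log_lik_indep(x_a, x_v, params)
    log_prior_odds = np.log(params.p_common) - np.log1p(-params.p_common)
    post = 1.0 / (1.0 + np.exp(-(log_lr + log_prior_odds)))
    return post[()] if isinstance(post, np.ndarray) and post.ndim == 0 else post


def fused_estimate(x_a, x_v, params: BCIParams):
    """Reliability-weighted fusion of both measurements and the prior."""
    wa = 1.0 / params.sigma_a**2
    wv = 1.0 / params.sigma_v**2
    wp = 1.0 / params.sigma_p**2
    return (np.asarray(x_a) * wa + np.asarray(x_v) * wv + params.mu_p * wp) / (
        wa + wv + wp
    )


def segregated_estimate(x, sigma: float, params: BCIParams):
    """Unisensory estimate: shrink the measurement toward the numeric prior."""
    if not sigma > 0:
        raise ValueError("sigma must be strictly positive")
    w = 1.0 / sigma**2
    wp = 1.0 / params.sigma_p**2
    return (np.asarray(x) * w + params.mu_p * wp) / (w + wp)


def compute_estimates(
    x_a,
    x_v,
    params: BCIParams,
    task: Task,
    rng: np.random.Generator | None = None,
    p_common_trial=None,
) -> EstimateSet:
    """All observer estimates for given internal samples.

    ``p_common_trial`` optionally overrides the causal prior per trial (used
    when prestimulus state modulates the effective prior); it must broadcast
    against ``x_a``.
    """
    x_a = np.atleast_1d(np.asarray(x_a, dtype=float))
    x_v = np.atleast_1d(np.asarray(x_v, dtype=float))
    fused = fused_estimate(x_a, x_v, params)
    seg_a = segregated_estimate(x_a, params.sigma_a, params)
    seg_v = segregated_estimate(x_v, params.sigma_v, params)
    if p_common_trial is None:
        post = np.broadcast_to(
            np.asarray(posterior_common(x_a, x_v, params)), x_a.shape
        ).astype(float)
    else:
        log_lr = _log_lik_common(x_a, x_v, params) - _log_lik_indep(x_a, x_v, params)
        pc = np.clip(np.asarray(p_common_trial, dtype=float), 0.0, 1.0)
        with np.errstate(divide="ignore"):
            log_odds = log_lr + np.log(pc) - np.log1p(-pc)
        post = 1.0 / (1.0 + np.exp(-log_odds))
        post = np.where(pc == 0.0, 0.0, np.where(pc == 1.0, 1.0, post))
    seg_task = seg_a if task == "A" else seg_v

    if params.strategy == "model_averaging":
        final = post * fused + (1.0 - post) * seg_task
    elif params.strategy == "model_selection":
        # posterior <= 0.5 reports the segregation estimate
        final = np.where(post > 0.5, fused, seg_task)
    else:  # probability_matching
        if rng is None:
            raise ValueError("probability_matching requires an rng")
        alpha = rng.uniform(size=post.shape)
        final = np.where(post > alpha, fused, seg_task)
    return EstimateSet(fused, seg_a, seg_v, final, post)


def final_estimate(
    x_a, x_v, params: BCIParams, task: Task, rng: np.random.Generator | None = None
) -> EstimateSet:
    """Alias of :func:`compute_estimates`; kept for the operation name."""
    return compute_estimates(x_a, x_v, params, task, rng=rng)


def nearest_button(values) -> np.ndarray:
    """Map continuous estimates to buttons {1..4} by proximity.

    Values below 1.5 map to 1 and above 3.5 to 4; half-integer ties round up.
    """
    v = np.floor(np.asarray(values, dtype=float) + 0.5)  # round half-up
    return np.clip(v, 1, N_BUTTONS).astype(int)


# ---------------------------------------------------------------------------
# Marginal response distributions and trial simulation
# ---------------------------------------------------------------------------


def _sample_measurements(
    condition: tuple[int, int, str],
    params: BCIParams,
    n_samples: int,
    rng: np.random.Generator | None = None,
    draws: np.ndarray | None = None,
):
    """Internal samples x_A, x_V for one condition.

    ``draws`` may hold pre-drawn standard normals of shape (2, n_samples); the
    fitting code passes a fixed set so that likelihood evaluations use common
    random numbers across parameter proposals.
    """
    n_a, n_v, _ = condition
    if draws is None:
        if rng is None:
            raise ValueError("either rng or draws is required")
        draws = rng.standard_normal((2, n_samples))
    x_a = n_a + params.sigma_a * draws[0]
    x_v = n_v + params.sigma_v * draws[1]
    return x_a, x_v


def predict_condition_distribution(
    params: BCIParams,
    condition: tuple[int, int, str],
    n_samples: int = 5000,
    rng: np.random.Generator | None = None,
    draws: np.ndarray | None = None,
) -> ConditionDistribution:
    """Monte-Carlo marginal p(response | condition) over internal samples."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    x_a, x_v = _sample_measurements(condition, params, n_samples, rng, draws)
    est = compute_estimates(x_a, x_v, params, condition[2], rng=rng)
    buttons = nearest_button(est.n_final)
    probs = np.bincount(buttons, minlength=N_BUTTONS + 1)[1:] / buttons.size
    return ConditionDistribution(condition, probs)


def predict_all_conditions(
    params: BCIParams,
    n_samples: int = 5000,
    rng: np.random.Generator | None = None,
    draws: np.ndarray | None = None,
) -> np.ndarray:
    """(32, 4) predicted response probabilities, rows in CONDITIONS order.

    ``draws`` of shape (2, 32, n_samples) enables common random numbers.
    """
    out = np.empty((len(CONDITIONS), N_BUTTONS))
    for i, cond in enumerate(CONDITIONS):
        d = None if draws is None else draws[:, i, :]
        out[i] = predict_condition_distribution(
            params, cond, n_samples, rng=rng, draws=d
        ).probs
    return out


def simulate_trials(
    params: BCIParams,
    design: pd.DataFrame,
    rng: np.random.Generator,
    p_common_trial=None,
    return_estimates: bool = False,
):
    """Simulate responses for a design table (columns task, n_aud, n_vis).

    Draws per-trial sensory samples, runs the observer, and maps the final
    estimate to the nearest button.  ``p_common_trial`` optionally supplies a
    trial-wise effective causal prior (same length as the design).
    """
    design = design.reset_index(drop=True)
    n = len(design)
    x_a = design["n_aud"].to_numpy(float) + params.sigma_a * rng.standard_normal(n)
    x_v = design["n_vis"].to_numpy(float) + params.sigma_v * rng.standard_normal(n)
    responses = np.empty(n, dtype=int)
    store = {} if return_estimates else None
    for task in ("A", "V"):
        mask = (design["task"] == task).to_numpy()
        if not mask.any():
            continue
        pc = None if p_common_trial is None else np.asarray(p_common_trial)[mask]
        est = compute_estimates(
            x_a[mask], x_v[mask], params, task, rng=rng, p_common_trial=pc
        )
        responses[mask] = nearest_button(est.n_final)
        if store is not None:
            store[task] = (mask, est)
    out = design.copy()
    out["response"] = responses
    if not return_estimates:
        return out
    est_full = EstimateSet(*(np.empty(n) for _ in range(5)))
    for mask, est in store.values():
        for f in ("n_fused", "n_aud_seg", "n_vis_seg", "n_final", "post_common"):
            getattr(est_full, f)[mask] = getattr(est, f)
    return out, est_full


# ---------------------------------------------------------------------------
# Trial-table text interface
# ---------------------------------------------------------------------------


def read_trial_table(path) -> pd.DataFrame:
    """Read a delimited trial table (comma or tab separated) and validate it."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if not df["task"].isin(["A", "V"]).all():
        raise ValueError("task must be 'A' or 'V'")
    for col in ("n_aud", "n_vis", "response"):
        if not df[col].isin(range(1, N_BUTTONS + 1)).all():
            raise ValueError(f"{col} must lie in 1..{N_BUTTONS}")
    return df


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
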
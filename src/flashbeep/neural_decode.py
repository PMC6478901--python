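"""Spatio-temporal pattern binning, SVR decoding and the neural w_AV.

Continuous multichannel activity is cut into 20 ms bins; the samples within a
bin are concatenated across channels into one spatio-temporal feature vector
(64 channels x 4 samples = 256 features at 200 Hz) and z-scored per feature.
A linear support-vector regression learns the mapping from patterns to the
stimulus count on audiovisually congruent trials (labels recoded to
{-1, -0.33, 0.33, 1}) in a leave-one-run-out scheme with a nested grid search
over (C, nu), and generalises to all trials of the held-out run.  Decoded
estimates are z-scored within run, feed decoding-accuracy inference
(Fisher-z Pearson r, sign-flip cluster test) and the time-resolved neural
w_AV with cluster-corrected circular LRTS effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold
from sklearn.svm import NuSVR

from . import behavior_wav, stats_core
from .stats_core import DEFAULT_N_PERM

#: stimulus count -> SVR training label
LABEL_MAP = {1: -1.0, 2: -0.33, 3: 0.33, 4: 1.0}

SVR_C_GRID = (0.1, 1.0, 10.0)
SVR_NU_GRID = (0.2, 0.5, 0.8)


@dataclass
class PatternSeries:
    """trials x features x time-bins activity with trial metadata."""

    data: np.ndarray
    bin_times: np.ndarray
    trials: pd.DataFrame
    bin_width_s: float = 0.02

    def __post_init__(self):
        if self.data.shape[0] != len(self.trials):
            raise ValueError("data and trial metadata disagree on trial count")
        if np.any(np.diff(self.bin_times) <= 0):
            raise ValueError("bin times must be strictly increasing")


@dataclass
class DecodedSeries:
    """Per-trial decoded estimate per time-bin, z-scored within run."""

    estimates: np.ndarray  # (n_trials, n_bins)
    bin_times: np.ndarray
    trials: pd.DataFrame
    fold: np.ndarray = None  # held-out run per trial


def _zscore_features(x: np.ndarray) -> np.ndarray:
    """z-score across trials; (numerically) zero-variance features become 0."""
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    ok = sd > 1e-10 * (np.abs(mu) + 1.0)
    return np.where(ok, (x - mu) / np.where(ok, sd, 1.0), 0.0)


def bin_patterns(
    continuous: np.ndarray,
    sfreq: float,
    trials: pd.DataFrame,
    window_s: float = 0.02,
    t_start: float = 0.0,
) -> PatternSeries:
    """Bin (trials x channels x samples) into z-scored spatio-temporal patterns.

    The window must align with the sampling grid; the first sample's time
    labels each bin.
    """
    n_trials, n_chan, n_samp = continuous.shape
    per_bin = window_s * sfreq
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise ValueError("window is not aligned to the sampling grid")
    per_bin = int(round(per_bin))
    n_bins = n_samp // per_bin
    x = continuous[:, :, : n_bins * per_bin].reshape(
        n_trials, n_chan, n_bins, per_bin
    )
    # concatenate channels x within-bin samples -> features
    feats = x.transpose(0, 2, 1, 3).reshape(n_trials, n_bins, n_chan * per_bin)
    feats = feats.transpose(0, 2, 1)  # (trials, features, bins)
    for b in range(n_bins):
        feats[:, :, b] = _zscore_features(feats[:, :, b])
    bin_times = t_start + np.arange(n_bins) * window_s
    return PatternSeries(feats, bin_times, trials.reset_index(drop=True),
                         bin_width_s=window_s)


# ---------------------------------------------------------------------------
# SVR decoding with leave-one-run-out nested cross-validation
# ---------------------------------------------------------------------------


def _congruent_mask(trials: pd.DataFrame) -> np.ndarray:
    return (trials["n_aud"] == trials["n_vis"]).to_numpy()


def _grid_search_svr(X, y, groups, c_grid, nu_grid):
    """Inner CV over training runs; returns the best fitted estimator."""
    n_groups = np.unique(groups).size
    n_splits = min(3, n_groups)
    best = (None, -np.inf)
    for C in c_grid:
        for nu in nu_grid:
            scores = []
            if n_splits >= 2:
                cv = GroupKFold(n_splits=n_splits)
                for tr, te in cv.split(X, y, groups):
                    m = NuSVR(kernel="linear", C=C, nu=nu).fit(X[tr], y[tr])
                    pred = m.predict(X[te])
                    if np.std(pred) > 0 and np.std(y[te]) > 0:
                        scores.append(np.corrcoef(pred, y[te])[0, 1])
                    else:
                        scores.append(-np.mean((pred - y[te]) ** 2))
            score = np.mean(scores) if scores else 0.0
            if score > best[1]:
                best = ((C, nu), score)
    C, nu = best[0]
    return NuSVR(kernel="linear", C=C, nu=nu).fit(X, y)


def decode_number(
    patterns: PatternSeries,
    train_on_congruent: bool = True,
    per_task_training: bool = False,
    c_grid=SVR_C_GRID,
    nu_grid=SVR_NU_GRID,
) -> DecodedSeries:
    """Leave-one-run-out SVR decoding of stimulus number at every time-bin.

    Training uses congruent trials of all-but-one run (pooled over report
    tasks by default); the fitted model predicts every trial of the held-out
    run.  Predictions are z-scored within each run.
    """
    trials = patterns.trials
    runs = trials["run"].to_numpy()
    run_ids = np.unique(runs)
    if run_ids.size < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out CV")
    congruent = _congruent_mask(trials)
    labels = trials["n_aud"].map(LABEL_MAP).to_numpy(float)

    n_trials, _, n_bins = patterns.data.shape
    est = np.full((n_trials, n_bins), np.nan)
    fold = np.empty(n_trials, dtype=runs.dtype)
    task = trials["task"].to_numpy()
    task_groups = [None] if not per_task_training else ["A", "V"]
    for b in range(n_bins):
        X = patterns.data[:, :, b]
        for held in run_ids:
            test = runs == held
            for tg in task_groups:
                tmask = np.ones(n_trials, bool) if tg is None else task == tg
                train = (~test) & congruent & tmask
                if train.sum() < 8:
                    raise ValueError("fold with <8 training trials")
                model = _grid_search_svr(
                    X[train], labels[train], runs[train], c_grid, nu_grid
                )
                pred_mask = test & tmask
                est[pred_mask, b] = model.predict(X[pred_mask])
            fold[test] = held
    # z-score within run (per bin)
    for r in run_ids:
        m = runs == r
        mu = est[m].mean(axis=0, keepdims=True)
        sd = est[m].std(axis=0, keepdims=True)
        est[m] = (est[m] - mu) / np.where(sd > 0, sd, 1.0)
    return DecodedSeries(est, patterns.bin_times, trials, fold)


def decoding_accuracy(decoded: DecodedSeries) -> np.ndarray:
    """Per-bin Pearson r between true and decoded number, congruent trials."""
    mask = _congruent_mask(decoded.trials)
    true = decoded.trials.loc[mask, "n_aud"].to_numpy(float)
    out = np.empty(decoded.estimates.shape[1])
    for b in range(out.size):
        pred = decoded.estimates[mask, b]
        if np.std(pred) == 0 or np.std(true) == 0:
            out[b] = 0.0
        else:
            out[b] = np.corrcoef(true, pred)[0, 1]
    return out


def decoding_accuracy_test(
    accuracy_maps: np.ndarray,
    threshold: float = 2.0,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
) -> stats_core.ClusterTestResult:
    """Group test of Fisher-z decoding accuracy > 0 with cluster correction.

    ``accuracy_maps``: (n_participants, n_bins) Pearson r values.
    """
    z = stats_core.fisher_z(np.asarray(accuracy_maps))
    return stats_core.cluster_randomization_test(
        z, threshold=threshold, n_perm=n_perm, tail="greater", rng=rng
    )


# ---------------------------------------------------------------------------
# Neural w_AV time courses
# ---------------------------------------------------------------------------


def neural_wav_timecourse(decoded: DecodedSeries) -> np.ndarray:
    """w_AV per time-bin and cell from decoded estimates for one participant.

    Returns angles in radians of shape (n_bins, 2 tasks, 2 disparities), cells
    ordered (A, V) x (small, large).
    """
    trials = decoded.trials.copy()
    trials["disparity"] = behavior_wav.disparity_label(
        trials["n_aud"], trials["n_vis"]
    )
    n_bins = decoded.estimates.shape[1]
    out = np.full((n_bins, 2, 2), np.nan)
    for j, task in enumerate(behavior_wav.TASKS):
        for k, disp in enumerate(behavior_wav.DISPARITIES):
            cell = (trials["task"] == task) & (trials["disparity"] == disp)
            sub = trials.loc[cell]
            na = sub["n_aud"].to_numpy(float)
            nv = sub["n_vis"].to_numpy(float)
            X = np.column_stack([np.ones(len(sub)), na, nv])
            pinv = np.linalg.pinv(X)
            for b in range(n_bins):
                beta = pinv @ decoded.estimates[cell.to_numpy(), b]
                out[b, j, k] = np.arctan2(beta[2], beta[1])
    return out


def neural_wav_test(
    wav_maps: np.ndarray,
    effect: str,
    threshold: float = 2.0,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
) -> stats_core.ClusterTestResult:
    """Cluster-corrected circular LRTS effect over time.

    ``wav_maps``: (n_participants, n_bins, 2, 2) angles in radians.  The LRTS
    is computed per time-bin; cluster mass is the summed LRTS above the
    auxiliary threshold (default 2) and the null uses the same
    within-participant randomization at every time-bin simultaneously (the
    cell permutation is drawn once per participant and applied across time,
    preserving temporal dependence).
    """
    rng = np.random.default_rng() if rng is None else rng
    maps = np.asarray(wav_maps)
    n_subj, n_bins = maps.shape[:2]
    # time as leading axis for the vectorised LRTS: (n_bins, n_subj, 2, 2)
    w_t = maps.transpose(1, 0, 2, 3)
    obs = _lrts_over_time(w_t, effect)
    null = np.empty((n_perm, n_bins))
    for p in range(n_perm):
        perm = _permute_cells_consistent(maps, effect, rng)
        null[p] = _lrts_over_time(perm.transpose(1, 0, 2, 3), effect)
    return stats_core.cluster_test_from_custom_stat(
        obs, null, threshold=threshold, tail="greater"
    )


def _lrts_over_time(w_t: np.ndarray, effect: str) -> np.ndarray:
    return behavior_wav._lrts(w_t, effect)


def _permute_cells_consistent(maps, effect, rng):
    """One within-participant cell randomization applied across all bins."""
    n_subj = maps.shape[0]
    res = maps.copy()
    if effect == "task":
        bits = rng.integers(0, 2, size=(n_subj, 2)).astype(bool)  # per disparity
        sw = maps[..., ::-1, :]
        res = np.where(bits[:, None, None, :], sw, maps)
    elif effect == "disparity":
        bits = rng.integers(0, 2, size=(n_subj, 2)).astype(bool)  # per task
        sw = maps[..., :, ::-1]
        res = np.where(bits[:, None, :, None], sw, maps)
    elif effect == "interaction":
        bits = rng.integers(0, 2, size=(n_subj, 2)).astype(bool)
        b1 = bits[:, 0][:, None]
        b2 = bits[:, 1][:, None]
        res[..., 0, 0] = np.where(b1, maps[..., 1, 1], maps[..., 0, 0])
        res[..., 1, 1] = np.where(b1, maps[..., 0, 0], maps[..., 1, 1])
        res[..., 0, 1] = np.where(b2, maps[..., 1, 0], maps[..., 0, 1])
        res[..., 1, 0] = np.where(b2, maps[..., 0, 1], maps[..., 1, 0])
    else:
        raise ValueError(f"unknown effect {effect!r}")
    return res


# ---------------------------------------------------------------------------
# Univariate ERP audiovisual-interaction contrast
# ---------------------------------------------------------------------------


def erp_interaction(
    av: np.ndarray,
    a: np.ndarray,
    v: np.ndarray,
    threshold: float = 2.0,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
):
    """AV - (A + V) difference wave with a two-sided sign-flip cluster test.

    Inputs are per-participant channel-average time courses of matching shape
    (n_participants, n_times).  Returns (difference_waves, ClusterTestResult).
    """
    av, a, v = (np.asarray(x, dtype=float) for x in (av, a, v))
    if not av.shape == a.shape == v.shape:
        raise ValueError("mismatched time axes")
    diff = av - (a + v)
    result = stats_core.cluster_randomization_test(
        diff, threshold=threshold, n_perm=n_perm, tail="two-sided", rng=rng
    )
    return diff, result
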
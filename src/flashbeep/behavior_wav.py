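"""Audiovisual weight index w_AV and circular inference.

w_AV quantifies the relative influence of the true number of beeps and
flashes on a numeric report (or on a decoded neural estimate): within each
cell of the 2 (numeric disparity: small <=1 vs large >=2) x 2 (task: auditory
vs visual report) design, the report is regressed on the true auditory and
visual counts and w_AV = atan2(beta_V, beta_A) in degrees, so 0 deg means a
purely auditory and 90 deg a purely visual influence.

Group inference on the angles is fully randomization-based: a likelihood-ratio
test statistic (LRTS) from von Mises mean-direction models for the factorial
effects, sign-flip tests of the mean circular distance for one-sample
questions, and bootstrap confidence intervals for circular means.  The von
Mises concentration is a single ML-estimated nuisance parameter shared across
cells under each hypothesis; the interaction null is the additive model on the
circle, whose ML profile reduces to a one-dimensional search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import bci_core, stats_core
from .bci_core import CONDITIONS, BCIParams
from .stats_core import DEFAULT_N_PERM, circ_dist, vonmises_loglik

TASKS = ("A", "V")
DISPARITIES = ("small", "large")


@dataclass
class CircularTestResult:
    statistic: float
    p_value: float
    effect: str
    n_perm: int
    meta: dict | None = None


def disparity_label(n_aud, n_vis):
    return np.where(np.abs(np.asarray(n_aud) - np.asarray(n_vis)) <= 1,
                    "small", "large")


def compute_wav(
    trials: pd.DataFrame, response_col: str = "response"
) -> pd.DataFrame:
    """Per-participant per-cell regression slopes and w_AV angle (degrees)."""
    df = trials.copy()
    df["disparity"] = disparity_label(df["n_aud"], df["n_vis"])
    rows = []
    for (pid, task, disp), cell in df.groupby(
        ["participant", "task", "disparity"], sort=True
    ):
        rows.append(
            {"participant": pid, "task": task, "disparity": disp}
            | _cell_regression(cell, response_col)
        )
    return pd.DataFrame(rows)


def _cell_regression(cell: pd.DataFrame, response_col: str) -> dict:
    na = cell["n_aud"].to_numpy(float)
    nv = cell["n_vis"].to_numpy(float)
    if np.unique(na).size < 2 or np.unique(nv).size < 2:
        raise ValueError("need >=2 distinct values of each true count per cell")
    X = np.column_stack([np.ones(len(cell)), na, nv])
    y = cell[response_col].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    w = np.degrees(np.arctan2(beta[2], beta[1]))
    return {"beta_a": beta[1], "beta_v": beta[2], "w_av": w}


# ---------------------------------------------------------------------------
# Model-predicted w_AV via per-condition KDE modes
# ---------------------------------------------------------------------------


def condition_modes(
    params: BCIParams,
    n_sim: int = 10_000,
    rng: np.random.Generator | None = None,
    estimates: tuple[str, ...] = ("n_final",),
) -> pd.DataFrame:
    """Kernel-density-estimated mode of each internal estimate per condition.

    Simulates fresh internal samples for every one of the 32 conditions and
    takes the mode of the Gaussian-KDE-smoothed distribution of the requested
    estimate(s).  Returns one row per condition.
    """
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for na, nv, task in CONDITIONS:
        x_a = na + params.sigma_a * rng.standard_normal(n_sim)
        x_v = nv + params.sigma_v * rng.standard_normal(n_sim)
        est = bci_core.compute_estimates(x_a, x_v, params, task, rng=rng)
        row = {"n_aud": na, "n_vis": nv, "task": task}
        for name in estimates:
            row[name + "_mode"] = _kde_mode(getattr(est, name))
            row[name + "_mean"] = float(np.mean(getattr(est, name)))
        rows.append(row)
    return pd.DataFrame(rows)


def _kde_mode(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if np.ptp(values) < 1e-12:
        return float(values[0])
    kde = stats.gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def predicted_wav(
    params: BCIParams,
    n_sim: int = 10_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Model-predicted w_AV per cell, computed on per-condition KDE modes."""
    modes = condition_modes(params, n_sim=n_sim, rng=rng)
    modes["disparity"] = disparity_label(modes["n_aud"], modes["n_vis"])
    rows = []
    for (task, disp), cell in modes.groupby(["task", "disparity"], sort=True):
        rows.append(
            {"task": task, "disparity": disp}
            | _cell_regression(cell, "n_final_mode")
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Circular LRTS factorial randomization tests
# ---------------------------------------------------------------------------


def _wav_array(wav: pd.DataFrame) -> np.ndarray:
    """(n_subj, 2 tasks, 2 disparities) angles in radians, cells ordered
    (A, V) x (small, large)."""
    pids = sorted(wav["participant"].unique())
    out = np.full((len(pids), 2, 2), np.nan)
    for _, row in wav.iterrows():
        i = pids.index(row["participant"])
        j = TASKS.index(row["task"])
        k = DISPARITIES.index(row["disparity"])
        out[i, j, k] = np.radians(row["w_av"])
    if np.isnan(out).any():
        raise ValueError("unbalanced design: every participant needs all 4 cells")
    return out


def _loglik_grouped(z_groups: np.ndarray, n_total: int) -> np.ndarray:
    """Max von Mises log lik for a mean-per-group model.

    ``z_groups``: complex resultants per group, groups along the last axis;
    leading axes (e.g. permutations) are preserved.
    """
    cbar = np.abs(z_groups).sum(axis=-1) / n_total
    return vonmises_loglik(n_total, cbar)


def _additive_loglik(z_cells: np.ndarray, n_total: int, n_grid: int = 720):
    """Max log lik of the additive circular model mu_jk = mu + a_j + b_k.

    ``z_cells``: complex resultants with shape (..., 2, 2).  Profiling out mu
    and a analytically leaves max_b |z00 + z01 e^{-ib}| + |z10 + z11 e^{-ib}|,
    solved on a dense grid over b.
    """
    b = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    e = np.exp(-1j * b)
    h = np.abs(z_cells[..., 0, 0, None] + z_cells[..., 0, 1, None] * e) + np.abs(
        z_cells[..., 1, 0, None] + z_cells[..., 1, 1, None] * e
    )
    cbar = h.max(axis=-1) / n_total
    return vonmises_loglik(n_total, cbar)


def _lrts(w: np.ndarray, effect: str, n_grid: int = 720) -> np.ndarray:
    """LRTS for one effect; ``w`` has shape (..., n_subj, 2, 2) in radians."""
    z = np.exp(1j * w)
    n_total = w.shape[-3] * 4
    z_cells = z.sum(axis=-3)  # (..., 2, 2)
    if effect == "task":
        full = _loglik_grouped(z_cells.sum(axis=-1), n_total)
        null = _loglik_grouped(z_cells.sum(axis=(-1, -2))[..., None], n_total)
    elif effect == "disparity":
        full = _loglik_grouped(z_cells.sum(axis=-2), n_total)
        null = _loglik_grouped(z_cells.sum(axis=(-1, -2))[..., None], n_total)
    elif effect == "interaction":
        full = _loglik_grouped(
            z_cells.reshape(z_cells.shape[:-2] + (4,)), n_total
        )
        null = _additive_loglik(z_cells, n_total, n_grid=n_grid)
    else:
        raise ValueError(f"unknown effect {effect!r}")
    return 2.0 * (full - null)


def _permute(w: np.ndarray, effect: str, n_perm: int, rng) -> np.ndarray:
    """Within-participant randomizations; returns (n_perm, n, 2, 2)."""
    n = w.shape[0]
    out = np.broadcast_to(w, (n_perm,) + w.shape).copy()
    if effect == "task":
        # swap task labels within each disparity level
        bits = rng.integers(0, 2, size=(n_perm, n, 2)).astype(bool)
        sw = out[..., ::-1, :]
        out = np.where(bits[..., None, :], sw, out)
    elif effect == "disparity":
        bits = rng.integers(0, 2, size=(n_perm, n, 2)).astype(bool)
        sw = out[..., :, ::-1]
        out = np.where(bits[..., :, None], sw, out)
    else:  # interaction: swap within the simple-effect pairs
        # pair 1: (A,small) <-> (V,large); pair 2: (A,large) <-> (V,small)
        bits = rng.integers(0, 2, size=(n_perm, n, 2)).astype(bool)
        res = out.copy()
        b1 = bits[..., 0]
        res[..., 0, 0] = np.where(b1, out[..., 1, 1], out[..., 0, 0])
        res[..., 1, 1] = np.where(b1, out[..., 0, 0], out[..., 1, 1])
        b2 = bits[..., 1]
        res[..., 0, 1] = np.where(b2, out[..., 1, 0], out[..., 0, 1])
        res[..., 1, 0] = np.where(b2, out[..., 0, 1], out[..., 1, 0])
        out = res
    return out


def circular_lrts_test(
    wav: pd.DataFrame | np.ndarray,
    effect: str,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
    n_grid: int = 720,
) -> CircularTestResult:
    """Randomization test of a factorial effect on the w_AV angles.

    Main effects permute the tested factor's labels within the levels of the
    other factor; the interaction permutes the simple-effect pairs.  All
    randomizations are within participant.  ``n_grid`` controls the angular
    resolution of the additive-model profile likelihood (interaction only).
    """
    rng = np.random.default_rng() if rng is None else rng
    w = _wav_array(wav) if isinstance(wav, pd.DataFrame) else np.asarray(wav)
    obs = float(_lrts(w, effect, n_grid=n_grid))
    perms = _permute(w, effect, n_perm, rng)
    null = _lrts(perms, effect, n_grid=n_grid)
    p = stats_core.perm_p(null, obs)
    return CircularTestResult(obs, p, effect, n_perm,
                              meta={"concentration": "common-kappa"})


def one_sample_circular_test(
    angles_deg,
    test_angle_deg: float,
    side: str = "two-sided",
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
) -> CircularTestResult:
    """Sign-flip randomization test of the mean circular distance from a
    reference angle (all angles in degrees)."""
    rng = np.random.default_rng() if rng is None else rng
    d = circ_dist(np.radians(np.asarray(angles_deg, float)),
                  np.radians(test_angle_deg))
    obs = float(np.mean(d))
    flips = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null = (flips * d[None]).mean(axis=1)
    if side == "greater":
        p = stats_core.perm_p(null, obs)
    elif side == "less":
        p = (1.0 + np.sum(null <= obs)) / (1.0 + n_perm)
    elif side == "two-sided":
        p = stats_core.perm_p(np.abs(null), abs(obs))
    else:
        raise ValueError(f"unknown side {side!r}")
    return CircularTestResult(np.degrees(obs), float(p), "one-sample", n_perm)


def circular_mean_ci(
    angles_deg,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    ci: float = 0.68,
) -> tuple[float, float, float]:
    """Circular mean and bootstrap percentile CI, all in degrees.

    The CI is formed on the (wrapped) deviations of bootstrap means from the
    full-sample mean so that it behaves sensibly across the -180/180 wrap.
    """
    rng = np.random.default_rng() if rng is None else rng
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size < 2:
        raise ValueError("need at least 2 angles")
    mean = stats_core.circ_mean(a)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    boot = stats_core.circ_mean(a[idx], axis=1)
    dev = circ_dist(boot, mean)
    lo, hi = np.percentile(dev, [50 * (1 - ci), 50 * (1 + ci)])
    return (
        float(np.degrees(mean)),
        float(np.degrees(mean + lo)),
        float(np.degrees(mean + hi)),
    )
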
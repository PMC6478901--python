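"""Shared inference machinery.

Sign-flip randomization engines with cluster-based multiple-comparison
correction over 1-D time and 2-D time-frequency grids, circular descriptive
statistics, circular-linear correlation, the Rayleigh test of uniformity,
Fisher's z transform, and a within-subject 2 x k repeated-measures ANOVA with
Greenhouse-Geisser correction.

All randomization tests respect within-participant exchangeability only and
report p-values with the plus-one correction p = (1 + #{null >= obs}) /
(1 + n_perm), so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special, stats

DEFAULT_N_PERM = 5000


def fisher_z(r):
    """Fisher's z transform, clipped away from +-1 to stay finite."""
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def perm_p(null: np.ndarray, observed: float) -> float:
    """Plus-one-corrected permutation p-value (one tail, >=)."""
    null = np.asarray(null)
    return (1.0 + np.sum(null >= observed)) / (1.0 + null.size)


# ---------------------------------------------------------------------------
# Circular descriptives
# ---------------------------------------------------------------------------


def circ_mean(angles, axis=None):
    """Circular mean of angles in radians."""
    angles = np.asarray(angles, dtype=float)
    return np.angle(np.exp(1j * angles).mean(axis=axis))


def circ_r(angles, axis=None):
    """Mean resultant length."""
    angles = np.asarray(angles, dtype=float)
    return np.abs(np.exp(1j * angles).mean(axis=axis))


def circ_dist(a, b):
    """Signed circular distance a - b wrapped to (-pi, pi]."""
    return np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))


def vonmises_kappa(rbar):
    """ML estimate of the von Mises concentration from the resultant length.

    Best & Fisher style inverse-A1 approximation; adequate for likelihood
    ratios of mean-direction models where kappa is a nuisance parameter.
    """
    r = np.clip(np.asarray(rbar, dtype=float), 0.0, 1.0 - 1e-10)
    small = r < 0.53
    mid = (r >= 0.53) & (r < 0.85)
    kappa = np.where(
        small,
        2 * r + r**3 + 5 * r**5 / 6,
        np.where(mid, -0.4 + 1.39 * r + 0.43 / (1 - r), 1 / (r**3 - 4 * r**2 + 3 * r)),
    )
    return kappa


def vonmises_loglik(n, cbar, kappa=None):
    """Maximised von Mises log likelihood given the mean cosine residual.

    ``cbar`` is (1/n) * sum cos(theta_i - mu_i) under the fitted means; with
    kappa at its ML value the log likelihood is n*(kappa*cbar - log(2 pi
    I0(kappa))).  Vectorised over leading axes of ``cbar``.
    """
    cbar = np.asarray(cbar, dtype=float)
    if kappa is None:
        kappa = vonmises_kappa(cbar)
    # log I0 via the exponentially scaled Bessel function for stability
    log_i0 = np.log(special.i0e(kappa)) + np.abs(kappa)
    return n * (kappa * cbar - np.log(2 * np.pi) - log_i0)


def rayleigh_test(angles):
    """Rayleigh test of circular uniformity.

    Returns (z, p) with z = n * Rbar**2 and the standard small-sample
    approximation for p.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n < 3:
        raise ValueError("need at least 3 angles")
    rbar = circ_r(angles)
    rn = rbar * n
    z = n * rbar**2
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - rn**2)) - (1 + 2 * n))
    return float(z), float(min(p, 1.0))


def circular_linear_correlation(angles, values) -> float:
    """Circular-linear correlation coefficient in [0, 1].

    Multiple correlation of the linear variable with (sin a, cos a):
    R = sqrt((r_cx^2 + r_sx^2 - 2 r_cx r_sx r_cs) / (1 - r_cs^2)).
    """
    angles = np.asarray(angles, dtype=float)
    values = np.asarray(values, dtype=float)
    if angles.size != values.size or angles.size < 3:
        raise ValueError("need matched inputs of length >= 3")
    if np.ptp(values) == 0:
        raise ValueError("values are constant; correlation undefined")
    s, c = np.sin(angles), np.cos(angles)
    rcx = np.corrcoef(c, values)[0, 1]
    rsx = np.corrcoef(s, values)[0, 1]
    rcs = np.corrcoef(s, c)[0, 1]
    num = rcx**2 + rsx**2 - 2 * rcx * rsx * rcs
    r2 = num / (1 - rcs**2)
    return float(np.sqrt(max(r2, 0.0)))


# ---------------------------------------------------------------------------
# Cluster-based randomization inference
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    """One supra-threshold cluster: member indices, summed statistic, p."""

    indices: np.ndarray
    mass: float
    p_value: float = np.nan
    sign: int = 1


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    stat_map: np.ndarray
    threshold: float
    tail: str
    n_perm: int
    null_max_mass: np.ndarray = field(default=None, repr=False)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < 0.05]

    def mask(self, alpha: float = 0.05) -> np.ndarray:
        m = np.zeros(self.stat_map.shape, dtype=bool)
        for c in self.clusters:
            if c.p_value < alpha:
                m[tuple(c.indices.T)] = True
        return m


def _label_clusters(mask: np.ndarray):
    """Connected components: 1-D contiguity or 4-connectivity on a 2-D grid."""
    if mask.ndim == 1:
        labels, n = ndimage.label(mask)
    elif mask.ndim == 2:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        labels, n = ndimage.label(mask, structure=structure)
    else:
        raise ValueError("only 1-D or 2-D statistic maps are supported")
    return labels, n


def find_clusters(stat_map: np.ndarray, threshold: float, tail: str) -> list[Cluster]:
    """Supra-threshold clusters and their mass (summed statistic)."""
    clusters: list[Cluster] = []
    signs = {"greater": [1], "less": [-1], "two-sided": [1, -1]}[tail]
    for sign in signs:
        labels, n = _label_clusters(sign * stat_map > threshold)
        for k in range(1, n + 1):
            idx = np.argwhere(labels == k)
            mass = float(stat_map[labels == k].sum())
            clusters.append(Cluster(indices=idx, mass=mass, sign=sign))
    return clusters


def max_cluster_mass(stat_map: np.ndarray, threshold: float, tail: str) -> float:
    """Largest |cluster mass| of a statistic map (0 when none survive)."""
    best = 0.0
    signs = {"greater": [1], "less": [-1], "two-sided": [1, -1]}[tail]
    for sign in signs:
        mask = sign * stat_map > threshold
        if mask.any():
            labels, n = _label_clusters(mask)
            sums = ndimage.sum_labels(stat_map, labels, index=np.arange(1, n + 1))
            if n:
                best = max(best, float(np.max(np.abs(sums))))
    return best


def attach_cluster_p(
    clusters: list[Cluster], null_max: np.ndarray
) -> list[Cluster]:
    for c in clusters:
        c.p_value = perm_p(null_max, abs(c.mass))
    return clusters


def _t_maps_signflip(maps: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """One-sample t maps after sign flips.

    maps : (n_subj, *grid); flips : (n_perm, n_subj) of +-1.
    Returns (n_perm, *grid).
    """
    n = maps.shape[0]
    flat = maps.reshape(n, -1)
    m = flips @ flat / n
    # E[(s*x)^2] = E[x^2] regardless of the sign flip
    sq = np.mean(flat**2, axis=0)[None, :]
    var = (sq - m**2) * n / (n - 1)
    var = np.maximum(var, 1e-300)
    t = m / np.sqrt(var / n)
    return t.reshape((flips.shape[0],) + maps.shape[1:])


def one_sample_t_map(maps: np.ndarray) -> np.ndarray:
    n = maps.shape[0]
    m = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    return m / np.maximum(sd, 1e-300) * np.sqrt(n)


def cluster_randomization_test(
    maps: np.ndarray,
    threshold: float = 2.0,
    n_perm: int = DEFAULT_N_PERM,
    tail: str = "two-sided",
    rng: np.random.Generator | None = None,
) -> ClusterTestResult:
    """One-sample sign-flip cluster test on per-participant statistic maps.

    ``maps`` has shape (n_participants, n_times) or (n_participants, n_freqs,
    n_times).  The group statistic is the one-sample t value per grid point;
    clusters are defined by |t| (or signed t for one-tailed tests) above
    ``threshold``, the cluster-level statistic is the summed t, and the null
    is the maximal cluster mass over participant-wise sign flips.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng() if rng is None else rng
    obs_t = one_sample_t_map(maps)
    clusters = find_clusters(obs_t, threshold, tail)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, maps.shape[0]))
    null_t = _t_maps_signflip(maps, flips)
    null_max = np.array([max_cluster_mass(t, threshold, tail) for t in null_t])
    attach_cluster_p(clusters, null_max)
    return ClusterTestResult(clusters, obs_t, threshold, tail, n_perm, null_max)


def cluster_test_from_custom_stat(
    observed_map: np.ndarray,
    null_maps: np.ndarray,
    threshold: float,
    tail: str = "greater",
) -> ClusterTestResult:
    """Cluster correction when the statistic map and its permutation null are
    computed externally (e.g. the circular LRTS over time)."""
    clusters = find_clusters(observed_map, threshold, tail)
    null_max = np.array([max_cluster_mass(m, threshold, tail) for m in null_maps])
    attach_cluster_p(clusters, null_max)
    return ClusterTestResult(
        clusters, observed_map, threshold, tail, len(null_maps), null_max
    )


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA (2 x k within-subject) with Greenhouse-Geisser
# ---------------------------------------------------------------------------


@dataclass
class RmAnovaEffect:
    F: float
    df1: float
    df2: float
    p_value: float
    partial_eta2: float
    gg_epsilon: float


def _gg_epsilon(diffs: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the covariance of within-subject scores."""
    k = diffs.shape[1]
    if k < 2:
        return 1.0
    S = np.cov(diffs, rowvar=False)
    # double-centred covariance
    S_dc = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    num = np.trace(S_dc) ** 2
    den = (k - 1) * np.sum(S_dc**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova_2xk(values: np.ndarray) -> dict[str, RmAnovaEffect]:
    """Two-way within-subject ANOVA on values of shape (n_subj, 2, k).

    Returns effects 'factor_a' (the 2-level factor), 'factor_b' (the k-level
    factor) and 'interaction'.  GG epsilon is applied to factor_b and the
    interaction (and trivially to factor_a when k == 2).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3 or y.shape[1] != 2:
        raise ValueError("values must have shape (n_subj, 2, k)")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported")
    n, a, b = y.shape
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    mean_a = y.mean(axis=(0, 2))
    mean_b = y.mean(axis=(0, 1))
    mean_ab = y.mean(axis=0)
    mean_sa = y.mean(axis=2)
    mean_sb = y.mean(axis=1)

    ss_a = n * b * np.sum((mean_a - grand) ** 2)
    ss_b = n * a * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((mean_sa - subj[:, None] - mean_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((mean_sb - subj[:, None] - mean_b[None, :] + grand) ** 2)
    resid = (
        y
        - mean_ab[None]
        - mean_sa[:, :, None]
        - mean_sb[:, None, :]
        + mean_a[None, :, None]
        + mean_b[None, None, :]
        + subj[:, None, None]
        - grand
    )
    ss_sab = np.sum(resid**2)

    ss_total = np.sum((y - grand) ** 2)

    def effect(ss_eff, ss_err, df_eff, df_err, eps):
        if ss_eff <= 1e-12 * max(ss_total, 1.0):  # no effect variance at all
            return RmAnovaEffect(0.0, df_eff * eps, df_err * eps, 1.0, 0.0, eps)
        F = (ss_eff / df_eff) / (ss_err / df_err)
        p = stats.f.sf(F, df_eff * eps, df_err * eps)
        eta = ss_eff / (ss_eff + ss_err)
        return RmAnovaEffect(
            float(F), df_eff * eps, df_err * eps, float(p), float(eta), eps
        )

    # epsilon from the subject x condition difference scores
    eps_b = _gg_epsilon(y.mean(axis=1))
    inter_scores = (y[:, 0, :] - y[:, 1, :])
    eps_ab = _gg_epsilon(inter_scores)

    return {
        "factor_a": effect(ss_a, ss_sa, a - 1, (n - 1) * (a - 1), 1.0),
        "factor_b": effect(ss_b, ss_sb, b - 1, (n - 1) * (b - 1), eps_b),
        "interaction": effect(
            ss_ab, ss_sab, (a - 1) * (b - 1), (n - 1) * (a - 1) * (b - 1), eps_ab
        ),
    }
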
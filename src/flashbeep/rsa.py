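"""Representational similarity analysis of the observer's numeric estimates.

Model representational dissimilarity matrices (RDMs) are the pairwise absolute
differences between a per-condition summary of one internal estimate (the
unisensory visual or auditory segregation estimate, the fused estimate, the
final causal-inference estimate, or the posterior probability of a common
cause) across the 32 conditions.  Neural RDMs are Mahalanobis distances
between condition-mean activity patterns under a shrinkage-regularised trial
noise covariance.  Model and neural geometry are compared by Spearman rank
correlation of the upper-triangular parts, with sign-flip cluster inference
over time, and a BIC-based protected exceedance probability decides which of
the four numeric estimates dominates the patterns at each time-bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import LedoitWolf

from . import model_fit, stats_core
from .bci_core import CONDITIONS
from .stats_core import DEFAULT_N_PERM

#: the four numeric estimates entering the exceedance comparison
NUMERIC_ESTIMATES = ("n_vis_seg", "n_aud_seg", "n_fused", "n_final")


@dataclass
class RDM:
    """32 x 32 symmetric non-negative dissimilarity matrix with labels."""

    values: np.ndarray
    labels: list = None
    source: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RDM must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("RDM must be symmetric")
        if np.any(np.diag(v) > 1e-9) or np.any(v < -1e-12):
            raise ValueError("RDM must be non-negative with zero diagonal")
        self.values = v
        if self.labels is None:
            self.labels = list(CONDITIONS) if v.shape[0] == len(CONDITIONS) else \
                list(range(v.shape[0]))

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        names = ["_".join(map(str, l)) if isinstance(l, tuple) else str(l)
                 for l in self.labels]
        return pd.DataFrame(self.values, index=names, columns=names)


def model_rdm(values, labels=None, source: str = "model") -> RDM:
    """Pairwise absolute distances between per-condition estimate values."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("need one value per condition")
    if np.isnan(v).any():
        raise ValueError("missing conditions")
    return RDM(np.abs(v[:, None] - v[None, :]), labels=labels, source=source)


def behavioral_rdm(trials: pd.DataFrame) -> RDM:
    """RDM of per-condition mean numeric reports for one participant."""
    means = (
        trials.groupby(["task", "n_aud", "n_vis"])["response"].mean()
    )
    vals = np.array(
        [means.loc[(t, na, nv)] for na, nv, t in CONDITIONS], dtype=float
    )
    return model_rdm(vals, source="behavior")


def average_rdms(rdms: list[RDM]) -> RDM:
    return RDM(
        np.mean([r.values for r in rdms], axis=0),
        labels=rdms[0].labels,
        source=rdms[0].source,
    )


# ---------------------------------------------------------------------------
# Neural RDMs
# ---------------------------------------------------------------------------


def neural_rdm(
    patterns: np.ndarray,
    condition_index: np.ndarray,
    n_conditions: int | None = None,
    shrinkage: str = "ledoit-wolf",
    source: str = "neural",
    noise_cov: np.ndarray | None = None,
) -> RDM:
    """Mahalanobis-distance RDM between condition-mean patterns.

    ``patterns``: (n_trials, n_features) for one time-bin; ``condition_index``
    assigns each trial to a condition (0-based).  The noise covariance is the
    covariance of the within-condition residuals, pooled across conditions and
    regularised by Ledoit-Wolf shrinkage toward the diagonal (the sample
    covariance is singular whenever features outnumber trials); pass
    ``noise_cov`` to use a fixed covariance instead.  With the self-estimated
    covariance the distances are invariant to rescaling all patterns; with a
    fixed covariance they scale with the patterns.
    """
    x = np.asarray(patterns, dtype=float)
    ci = np.asarray(condition_index)
    k = int(ci.max()) + 1 if n_conditions is None else n_conditions
    counts = np.bincount(ci, minlength=k)
    if np.any(counts < 2):
        raise ValueError("need >=2 trials per condition")
    means = np.stack([x[ci == c].mean(axis=0) for c in range(k)])
    resid = x - means[ci]
    if noise_cov is not None:
        cov = np.asarray(noise_cov, dtype=float)
    elif shrinkage == "ledoit-wolf":
        cov = LedoitWolf(assume_centered=True).fit(resid).covariance_
    elif shrinkage == "identity":
        cov = np.eye(x.shape[1]) * resid.var()
    else:
        raise ValueError(f"unknown shrinkage {shrinkage!r}")
    # whiten once, then Euclidean distances in the whitened space
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 1e-12 * evals.max())
    white = means @ evecs / np.sqrt(evals)
    diff = white[:, None, :] - white[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return RDM(d, source=source)


# ---------------------------------------------------------------------------
# RDM comparison and exceedance over numeric estimates
# ---------------------------------------------------------------------------


def rdm_correlation(neural: RDM, model: RDM) -> float:
    """Spearman rank correlation of the RDMs' upper-triangular parts."""
    a, b = neural.upper(), model.upper()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant RDM: rank correlation undefined")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def rdm_correlation_test(
    rho_maps: np.ndarray,
    threshold: float = 2.0,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
) -> stats_core.ClusterTestResult:
    """One-sided sign-flip cluster test on Fisher-z Spearman correlations.

    ``rho_maps``: (n_participants, n_bins) per-bin RDM correlations.
    """
    z = stats_core.fisher_z(np.asarray(rho_maps))
    return stats_core.cluster_randomization_test(
        z, threshold=threshold, n_perm=n_perm, tail="greater", rng=rng
    )


def rsa_bic(rho: np.ndarray, n_patterns: int) -> np.ndarray:
    """BIC of a one-regressor RDM model from explained variance rho^2."""
    r2 = np.clip(np.asarray(rho, dtype=float) ** 2, 0.0, 1.0 - 1e-12)
    return n_patterns * np.log(1.0 - r2) + np.log(n_patterns)


def estimate_exceedance(
    rho: np.ndarray,
    n_patterns: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-bin protected exceedance probabilities over the numeric estimates.

    ``rho``: (n_participants, n_bins, n_estimates) RDM correlations.  Each
    correlation is converted to a BIC (n log(1 - rho^2) + log n), the log
    evidence is -BIC/2, and the random-effects group comparison runs
    independently per time-bin.  Returns (n_bins, n_estimates) pEPs.
    """
    rho = np.asarray(rho, dtype=float)
    n_subj, n_bins, k = rho.shape
    rng = np.random.default_rng(0) if rng is None else rng
    out = np.empty((n_bins, k))
    for b in range(n_bins):
        evid = -0.5 * rsa_bic(rho[:, b, :], n_patterns)
        out[b] = model_fit.protected_exceedance(evid, rng=rng).pep
    return out
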
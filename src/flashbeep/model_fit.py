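"""Maximum-likelihood fitting of the causal-inference observer models.

The predicted response distribution for each of the 32 conditions is obtained
by marginalising over the internal measurements via Monte-Carlo simulation
(default 5000 samples per condition) and binning the final estimate by nearest
button.  One fixed set of standard-normal draws per fit supplies common random
numbers across parameter proposals, so the simulated likelihood is a
deterministic, optimisable function of the parameters.

Models: the full causal-inference observer (5 free parameters), forced fusion
(p_common fixed at 1) and full segregation (p_common fixed at 0), each with 4
free parameters.  Optimisation is best-of-initialisations Nelder-Mead on
transformed scales (logit for p_common, log for the SDs), seeded from a
coarse grid search.  Group-level comparison uses the BIC approximation of the
log model evidence and random-effects Bayesian model selection (protected
exceedance probabilities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .bci_core import CONDITIONS, N_BUTTONS, BCIParams, nearest_button

PROB_FLOOR_FACTOR = 10  # likelihood floor is 1 / (PROB_FLOOR_FACTOR * n_samples)


@dataclass
class FitConfig:
    n_samples: int = 5000
    n_starts: int = 10
    maxiter: int = 300
    xatol: float = 2e-3
    fatol: float = 0.01
    polish: bool = True  # restart the simplex once from the winning start
    grid_p_common: tuple = (0.1, 0.5, 0.9)
    grid_mu_p: tuple = (1.5, 2.5, 3.5)
    grid_sigma_p: tuple = (1.0, 3.0)
    grid_sigma: tuple = (0.3, 1.0, 2.0)


@dataclass
class FitResult:
    params: BCIParams
    loglik: float
    loglik_null: float
    n_trials: int
    n_free_params: int
    init_index: int
    converged: bool = True

    @property
    def r2(self) -> float:
        return nagelkerke_r2(self.loglik, self.loglik_null, self.n_trials)

    @property
    def bic_evidence(self) -> float:
        return self.loglik - 0.5 * self.n_free_params * np.log(self.n_trials)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "p_common": p.p_common,
            "mu_p": p.mu_p,
            "sigma_p": p.sigma_p,
            "sigma_a": p.sigma_a,
            "sigma_v": p.sigma_v,
            "strategy": p.strategy,
            "loglik": self.loglik,
            "r2": self.r2,
            "bic_evidence": self.bic_evidence,
            "n_trials": self.n_trials,
            "n_free_params": self.n_free_params,
            "init_index": self.init_index,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def counts_by_condition(trials: pd.DataFrame) -> np.ndarray:
    """(32, 4) response counts in CONDITIONS order."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    index = {cond: i for i, cond in enumerate(CONDITIONS)}
    counts = np.zeros((len(CONDITIONS), N_BUTTONS), dtype=float)
    grouped = trials.groupby(["n_aud", "n_vis", "task", "response"]).size()
    for (na, nv, task, resp), n in grouped.items():
        counts[index[(int(na), int(nv), task)], int(resp) - 1] += n
    return counts


def make_draws(rng: np.random.Generator, n_samples: int) -> np.ndarray:
    """Common random numbers for one fit: (3, 32, n_samples).

    Rows 0-1 are standard normals for x_A and x_V; row 2 holds the uniform
    alpha draws used by the probability-matching strategy.
    """
    draws = np.empty((3, len(CONDITIONS), n_samples))
    draws[:2] = rng.standard_normal((2, len(CONDITIONS), n_samples))
    draws[2] = rng.uniform(size=(len(CONDITIONS), n_samples))
    return draws


#: per-condition true counts and task, as arrays for vectorised simulation
_COND_NA = np.array([c[0] for c in CONDITIONS], dtype=float)
_COND_NV = np.array([c[1] for c in CONDITIONS], dtype=float)
_COND_TASK_A = np.array([c[2] == "A" for c in CONDITIONS])


def _predicted_probs(params: BCIParams, draws: np.ndarray) -> np.ndarray:
    """(32, 4) marginal response probabilities under common random numbers."""
    tables = _condition_tables(params, draws)
    return _probs_for_p_common(tables, params.p_common, params.strategy, draws)


def nll_from_counts(probs: np.ndarray, counts: np.ndarray, n_samples: int) -> float:
    floor = 1.0 / (PROB_FLOOR_FACTOR * n_samples)
    return float(-(counts * np.log(np.maximum(probs, floor))).sum())


def negative_log_likelihood(
    params: BCIParams,
    trials: pd.DataFrame,
    n_samples: int = 5000,
    rng: np.random.Generator | None = None,
    draws: np.ndarray | None = None,
) -> float:
    """-sum log p(response | condition) with Monte-Carlo condition marginals."""
    counts = counts_by_condition(trials)
    if draws is None:
        if rng is None:
            raise ValueError("either rng or draws is required")
        draws = make_draws(rng, n_samples)
    probs = _predicted_probs(params, draws)
    return nll_from_counts(probs, counts, draws.shape[2])


def null_loglik(n_trials: int) -> float:
    """Log likelihood of uniform guessing over the four buttons."""
    return -n_trials * np.log(N_BUTTONS)


def nagelkerke_r2(loglik: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's coefficient of determination against a stated null."""
    if n < 1:
        raise ValueError("n must be >= 1")
    num = 1.0 - np.exp((2.0 / n) * (loglik_null - loglik))
    den = 1.0 - np.exp((2.0 / n) * loglik_null)
    return float(num / den)


# ---------------------------------------------------------------------------
# Parameter transforms and optimisation
# ---------------------------------------------------------------------------

_LOGIT_CLIP = 1e-6


def _logit(p):
    p = np.clip(p, _LOGIT_CLIP, 1 - _LOGIT_CLIP)
    return np.log(p / (1 - p))


def _expit(x):
    return special.expit(x)


def _pack(params: BCIParams, model_kind: str) -> np.ndarray:
    theta = [params.mu_p, np.log(params.sigma_p), np.log(params.sigma_a),
             np.log(params.sigma_v)]
    if model_kind == "bci":
        theta = [_logit(params.p_common)] + theta
    return np.array(theta)


def _unpack(theta: np.ndarray, model_kind: str, strategy: str) -> BCIParams:
    if model_kind == "bci":
        pc, mu, lsp, lsa, lsv = theta
        p_common = float(_expit(pc))
    else:
        mu, lsp, lsa, lsv = theta
        p_common = 1.0 if model_kind == "fusion" else 0.0
    return BCIParams(
        p_common=p_common,
        mu_p=float(mu),
        sigma_p=float(np.exp(np.clip(lsp, -10, 10))),
        sigma_a=float(np.exp(np.clip(lsa, -10, 10))),
        sigma_v=float(np.exp(np.clip(lsv, -10, 10))),
        strategy=strategy,
    )


#: initial-simplex steps on the transformed scales
#: (logit p_common, mu_p, log sigma_p, log sigma_a, log sigma_v)
_SIMPLEX_STEPS = np.array([0.75, 0.3, 0.3, 0.15, 0.15])


def _initial_simplex(theta: np.ndarray, model_kind: str) -> np.ndarray:
    steps = _SIMPLEX_STEPS if model_kind == "bci" else _SIMPLEX_STEPS[1:]
    simplex = np.tile(theta, (theta.size + 1, 1))
    simplex[1:] += np.diag(steps)
    return simplex


def _grid_candidates(config: FitConfig, model_kind: str, strategy: str):
    pcs = config.grid_p_common if model_kind == "bci" else (
        (1.0,) if model_kind == "fusion" else (0.0,)
    )
    for pc in pcs:
        for mu in config.grid_mu_p:
            for sp in config.grid_sigma_p:
                for sa in config.grid_sigma:
                    for sv in config.grid_sigma:
                        yield BCIParams(pc, mu, sp, sa, sv, strategy)


def fit_model(
    trials: pd.DataFrame,
    model_kind: str = "bci",
    strategy: str = "model_averaging",
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Best-of-initialisations simplex ML fit for one participant.

    ``model_kind`` is 'bci' (5 free parameters), 'fusion' (p_common = 1) or
    'segregation' (p_common = 0), both with 4 free parameters.
    """
    if model_kind not in ("bci", "fusion", "segregation"):
        raise ValueError(f"unknown model_kind {model_kind!r}")
    config = config or FitConfig()
    rng = np.random.default_rng() if rng is None else rng
    counts = counts_by_condition(trials)
    n_trials = int(counts.sum())
    draws = make_draws(rng, config.n_samples)

    def objective(theta):
        params = _unpack(theta, model_kind, strategy)
        probs = _predicted_probs(params, draws)
        return nll_from_counts(probs, counts, config.n_samples)

    # coarse grid search, exploiting that for fixed SDs the per-sample
    # estimates and likelihood ratios do not depend on p_common
    scored = []
    pcs = config.grid_p_common if model_kind == "bci" else (
        (1.0,) if model_kind == "fusion" else (0.0,)
    )
    for mu in config.grid_mu_p:
        for sp in config.grid_sigma_p:
            for sa in config.grid_sigma:
                for sv in config.grid_sigma:
                    base = BCIParams(0.5, mu, sp, sa, sv, strategy)
                    tables = _condition_tables(base, draws)
                    for pc in pcs:
                        probs = _probs_for_p_common(tables, pc, strategy, draws)
                        nll = nll_from_counts(probs, counts, config.n_samples)
                        scored.append((nll, base.with_(p_common=pc)))
    scored.sort(key=lambda t: t[0])
    starts = [p for _, p in scored[: config.n_starts]]

    best = None
    converged = True
    for i, start in enumerate(starts):
        theta0 = _pack(start, model_kind)
        res = optimize.minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            options={
                "maxiter": config.maxiter,
                "xatol": config.xatol,
                "fatol": config.fatol,
                "initial_simplex": _initial_simplex(theta0, model_kind),
            },
        )
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x, i, res.success)
    nll, theta, init_index, success = best
    if config.polish:
        if model_kind == "bci":
            # coordinate sweep over p_common at the incumbent's remaining
            # parameters: the likelihood ridge between the causal prior and
            # the numeric prior traps the simplex otherwise
            inc = _unpack(theta, model_kind, strategy)
            tables = _condition_tables(inc, draws)
            pcs = _expit(np.linspace(-4.0, 4.0, 33))
            sweep = [
                nll_from_counts(
                    _probs_for_p_common(tables, pc, strategy, draws),
                    counts,
                    config.n_samples,
                )
                for pc in pcs
            ]
            k = int(np.argmin(sweep))
            if sweep[k] < nll:
                nll = sweep[k]
                theta = _pack(inc.with_(p_common=float(pcs[k])), model_kind)
        # a fresh simplex around the incumbent escapes premature collapse
        res = optimize.minimize(
            objective,
            theta,
            method="Nelder-Mead",
            options={
                "maxiter": config.maxiter,
                "xatol": config.xatol,
                "fatol": config.fatol,
                "initial_simplex": _initial_simplex(
                    np.asarray(theta), model_kind
                ),
            },
        )
        if res.fun < nll:
            nll, theta, success = res.fun, res.x, res.success
    if not success:
        warnings.warn(
            "simplex did not converge within maxiter; returning best-so-far",
            RuntimeWarning,
        )
        converged = False
    params = _unpack(theta, model_kind, strategy)
    n_free = 5 if model_kind == "bci" else 4
    return FitResult(
        params=params,
        loglik=-nll,
        loglik_null=null_loglik(n_trials),
        n_trials=n_trials,
        n_free_params=n_free,
        init_index=init_index,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Fast single-parameter machinery (decile refits, grid search)
# ---------------------------------------------------------------------------


def _condition_tables(params: BCIParams, draws: np.ndarray) -> dict:
    """Per-condition sample-level quantities that do not depend on p_common.

    For fixed sigmas and prior, the fused estimate, the task-relevant
    segregation estimate and the causal log likelihood ratio are independent
    of the causal prior, so a sweep over p_common only reweights them.
    """
    from .bci_core import _log_lik_common, _log_lik_indep, fused_estimate, \
        segregated_estimate

    x_a = _COND_NA[:, None] + params.sigma_a * draws[0]
    x_v = _COND_NV[:, None] + params.sigma_v * draws[1]
    fused = fused_estimate(x_a, x_v, params)
    seg = np.where(
        _COND_TASK_A[:, None],
        segregated_estimate(x_a, params.sigma_a, params),
        segregated_estimate(x_v, params.sigma_v, params),
    )
    log_lr = _log_lik_common(x_a, x_v, params) - _log_lik_indep(x_a, x_v, params)
    return {"fused": fused, "seg": seg, "log_lr": log_lr}


def _probs_for_p_common(
    tables: dict, p_common: float, strategy: str, draws: np.ndarray
) -> np.ndarray:
    """(32, 4) response probabilities for one causal-prior value."""
    fused, seg, log_lr = tables["fused"], tables["seg"], tables["log_lr"]
    if p_common <= 0.0:
        final = seg
    elif p_common >= 1.0:
        final = fused
    else:
        odds = log_lr + np.log(p_common) - np.log1p(-p_common)
        post = 1.0 / (1.0 + np.exp(-odds))
        if strategy == "model_averaging":
            final = post * fused + (1 - post) * seg
        elif strategy == "model_selection":
            final = np.where(post > 0.5, fused, seg)
        else:
            final = np.where(post > draws[2], fused, seg)
    buttons = nearest_button(final)
    n_samples = buttons.shape[1]
    probs = np.stack(
        [(buttons == b).sum(axis=1) / n_samples for b in range(1, N_BUTTONS + 1)],
        axis=1,
    )
    return probs


class SingleParamRefitter:
    """Refit p_common or sigma_v on trial subsets, all else fixed.

    Precomputes predicted condition distributions on a dense candidate grid
    once, so that each subset refit is a table lookup plus a parabolic
    refinement around the grid minimum.  Used for the decile sort-and-refit
    and stimulus-history analyses where thousands of refits are required.
    """

    def __init__(
        self,
        reference: BCIParams,
        which: str,
        rng: np.random.Generator,
        n_samples: int = 2000,
        n_grid: int = 41,
    ):
        if which not in ("p_common", "sigma_v"):
            raise ValueError("which must be 'p_common' or 'sigma_v'")
        self.which = which
        self.reference = reference
        self.n_samples = n_samples
        draws = make_draws(rng, n_samples)
        if which == "p_common":
            # logit-spaced candidates covering (0, 1)
            grid_logit = np.linspace(-5.0, 5.0, n_grid)
            self.grid = special.expit(grid_logit)
            tables = _condition_tables(reference, draws)
            self.prob_tables = np.stack(
                [
                    _probs_for_p_common(tables, pc, reference.strategy, draws)
                    for pc in self.grid
                ]
            )
        else:
            lo, hi = reference.sigma_v / 4.0, reference.sigma_v * 4.0
            self.grid = np.exp(np.linspace(np.log(lo), np.log(hi), n_grid))
            self.prob_tables = np.stack(
                [
                    _predicted_probs(reference.with_(sigma_v=sv), draws)
                    for sv in self.grid
                ]
            )
        floor = 1.0 / (PROB_FLOOR_FACTOR * n_samples)
        self.log_tables = np.log(np.maximum(self.prob_tables, floor))

    def refit(self, trials_subset: pd.DataFrame) -> float:
        counts = counts_by_condition(trials_subset)
        if counts.sum() < 32:
            warnings.warn(
                f"subset has only {int(counts.sum())} trials; refit is noisy",
                RuntimeWarning,
            )
        return self.refit_counts(counts)

    def refit_counts(self, counts: np.ndarray) -> float:
        nll = -(self.log_tables * counts[None]).sum(axis=(1, 2))
        k = int(np.argmin(nll))
        if 0 < k < len(self.grid) - 1:
            # parabolic refinement on the (transformed) grid axis
            x = (
                special.logit(self.grid[k - 1 : k + 2])
                if self.which == "p_common"
                else np.log(self.grid[k - 1 : k + 2])
            )
            y = nll[k - 1 : k + 2]
            denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
            a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
            b = (
                x[2] ** 2 * (y[0] - y[1])
                + x[1] ** 2 * (y[2] - y[0])
                + x[0] ** 2 * (y[1] - y[2])
            ) / denom
            if a > 0:
                xv = float(np.clip(-b / (2 * a), x[0], x[2]))
                return float(special.expit(xv)) if self.which == "p_common" else float(
                    np.exp(xv)
                )
        return float(self.grid[k])


def refit_single_parameter(
    trials_subset: pd.DataFrame,
    reference: BCIParams,
    which: str,
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """1-D ML refit of p_common or sigma_v on a trial subset."""
    config = config or FitConfig()
    rng = np.random.default_rng() if rng is None else rng
    refitter = SingleParamRefitter(
        reference, which, rng, n_samples=min(config.n_samples, 2000)
    )
    return refitter.refit(trials_subset)


# ---------------------------------------------------------------------------
# Random-effects group model comparison
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Protected exceedance probabilities over K candidate models."""

    pep: np.ndarray
    exceedance: np.ndarray
    expected_freq: np.ndarray
    bor: float
    alpha: np.ndarray


def protected_exceedance(
    evidence: np.ndarray,
    rng: np.random.Generator | None = None,
    n_samples: int = 100_000,
    alpha0: float = 1.0,
) -> GroupComparison:
    """Random-effects Bayesian model selection from log evidences.

    ``evidence`` has shape (n_participants, n_models) of BIC-approximated log
    model evidences.  A variational Dirichlet scheme estimates the population
    model frequencies; exceedance probabilities come from Monte-Carlo samples
    of the Dirichlet posterior and are protected by the Bayes omnibus risk
    (the posterior probability that all models are equally frequent):
    pEP = EP * (1 - BOR) + BOR / K.
    """
    lme = np.asarray(evidence, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 2 or lme.shape[1] < 2:
        raise ValueError("need >=2 participants and >=2 models")
    if not np.all(np.isfinite(lme)):
        raise ValueError("evidences must be finite")
    n, k = lme.shape
    rng = np.random.default_rng(0) if rng is None else rng

    alpha = np.full(k, alpha0, dtype=float)
    w = np.full((n, k), 1.0 / k)
    for _ in range(200):
        e_ln_r = special.digamma(alpha) - special.digamma(alpha.sum())
        log_u = lme + e_ln_r[None, :]
        log_u -= log_u.max(axis=1, keepdims=True)
        w_new = np.exp(log_u)
        w_new /= w_new.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + w_new.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < 1e-8:
            alpha, w = alpha_new, w_new
            break
        alpha, w = alpha_new, w_new

    samples = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(samples, axis=1)
    ep = np.bincount(winners, minlength=k) / n_samples

    # Bayes omnibus risk: free energy of the RFX model vs the null of equal
    # model frequencies.
    e_ln_r = special.digamma(alpha) - special.digamma(alpha.sum())
    w_safe = np.maximum(w, 1e-300)
    elj = (
        special.gammaln(k * alpha0)
        - k * special.gammaln(alpha0)
        + ((alpha0 - 1) * e_ln_r).sum()
        + (w * (lme + e_ln_r[None, :])).sum()
    )
    sqf = (
        special.gammaln(alpha).sum()
        - special.gammaln(alpha.sum())
        - ((alpha - 1) * e_ln_r).sum()
    )
    sqm = -(w * np.log(w_safe)).sum()
    f1 = elj + sqf + sqm
    f0 = (special.logsumexp(lme, axis=1) - np.log(k)).sum()
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))

    pep = ep * (1 - bor) + bor / k
    pep = pep / pep.sum()
    return GroupComparison(
        pep=pep,
        exceedance=ep,
        expected_freq=alpha / alpha.sum(),
        bor=bor,
        alpha=alpha,
    )


def group_report(fits: dict[str, list[FitResult]]) -> pd.DataFrame:
    """Tabular group summary per model: parameter mean +- SEM, R2, relBIC,
    pEP and percentage of within-participant BIC winners.

    ``fits`` maps model name -> list of per-participant FitResults, all lists
    in the same participant order.  relBIC is the summed BIC evidence relative
    to the first model in the mapping (more negative = worse).
    """
    names = list(fits)
    evid = np.array([[f.bic_evidence for f in fits[m]] for m in names]).T
    comp = protected_exceedance(evid)
    winners = np.argmax(evid, axis=1)
    rows = []
    ref_evid = evid[:, 0].sum()
    for j, m in enumerate(names):
        fl = fits[m]
        row = {"model": m}
        for pname in ("p_common", "mu_p", "sigma_p", "sigma_a", "sigma_v"):
            vals = np.array([getattr(f.params, pname) for f in fl])
            row[pname] = vals.mean()
            row[pname + "_sem"] = vals.std(ddof=1) / np.sqrt(len(vals))
        r2s = np.array([f.r2 for f in fl])
        row["r2"] = r2s.mean()
        row["r2_sem"] = r2s.std(ddof=1) / np.sqrt(len(r2s))
        row["rel_bic"] = ref_evid - evid[:, j].sum()
        row["pep"] = comp.pep[j]
        row["pct_winners"] = 100.0 * np.mean(winners == j)
        rows.append(row)
    return pd.DataFrame(rows)
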
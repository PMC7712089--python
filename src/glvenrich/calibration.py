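"""Bayesian calibration of the discrepancy parameters.

The 2s parameters theta = (delta0, delta1) carry independent U(-100, 0)
priors, further restricted to delta1 > -1 where the enriched system is well
defined.  The likelihood compares calibration observations with the
noiseless enriched-model trajectory started from each calibration scenario,
under the known Gaussian measurement-noise variance.  Sampling uses a
delayed-rejection adaptive Metropolis (DRAM) scheme: a Gaussian random-walk
whose covariance adapts to the chain history, with one smaller-scale
second-stage proposal tried whenever the first stage rejects.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .enriched_model import DiscrepancyParams, EnrichedModel, simulate_enriched_batch
from .glv_models import GLVModel, SolverError
from .observations import ObservationSet

__all__ = [
    "PosteriorSamples",
    "log_prior",
    "log_likelihood",
    "log_posterior",
    "dram_sample",
    "run_mcmc",
    "PRIOR_LO",
    "PRIOR_HI",
]

logger = logging.getLogger(__name__)

PRIOR_LO = -100.0
PRIOR_HI = 0.0

#: Calibration integrates the enriched ODE tens of thousands of times; these
#: looser tolerances are ample for residuals measured against noise with
#: standard deviation ~0.03.
CALIBRATION_SOLVER_OPTS: dict[str, Any] = {"method": "RK45", "rtol": 1e-6,
                                           "atol": 1e-8}


@dataclasses.dataclass(frozen=True)
class PosteriorSamples:
    """Post-burn-in MCMC output over the 2s discrepancy parameters.

    ``chain`` has one row per retained draw; columns are ordered
    [delta0_1..delta0_s, delta1_1..delta1_s] (names ``delta_<i>_<j>`` with
    j=0 for state coefficients, j=1 for derivative coefficients).
    """

    chain: np.ndarray
    log_post: np.ndarray
    acceptance_rate: float
    seed: int | None
    ess: np.ndarray
    rhat: np.ndarray

    @property
    def n_params(self) -> int:
        return self.chain.shape[1]

    @property
    def param_names(self) -> list[str]:
        s = self.n_params // 2
        return [f"delta_{i + 1}_0" for i in range(s)] + [
            f"delta_{i + 1}_1" for i in range(s)
        ]

    @property
    def posterior_mean(self) -> np.ndarray:
        return self.chain.mean(axis=0)

    def posterior_mean_params(self) -> DiscrepancyParams:
        return DiscrepancyParams.from_vector(self.posterior_mean)

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        """Equal-tailed credible interval per parameter, shape (2s, 2)."""
        a = 100 * (1 - level) / 2
        return np.percentile(self.chain, [a, 100 - a], axis=0).T

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.chain, columns=self.param_names)
        df["log_post"] = self.log_post
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _theta_vector(theta) -> np.ndarray:
    if isinstance(theta, DiscrepancyParams):
        return theta.to_vector()
    return np.asarray(theta, dtype=float)


def log_prior(theta) -> float:
    """Independent U(-100, 0) log-prior, -inf outside the box or where any
    delta1 <= -1 (the enriched model is undefined there, so such proposals
    carry zero posterior mass even though the box nominally allows them)."""
    t = _theta_vector(theta)
    s = t.size // 2
    if np.any(t < PRIOR_LO) or np.any(t > PRIOR_HI) or np.any(t[s:] <= -1.0):
        return -np.inf
    return t.size * np.log(1.0 / (PRIOR_HI - PRIOR_LO))


def log_likelihood(
    theta,
    obs_c: ObservationSet,
    partial: GLVModel,
    solver_opts: Mapping[str, Any] | None = None,
) -> float:
    """Gaussian log-likelihood of the calibration observations.

    One enriched-model trajectory per calibration scenario (integrated as a
    single stacked system), evaluated at the observation times; residuals are
    scored under N(0, sigma_eps_sq).  Solver failures are treated as
    inadmissible proposals (-inf) with a logged warning.
    """
    t = _theta_vector(theta)
    s = t.size // 2
    if np.any(t > 0) or np.any(t[s:] <= -1.0):
        return -np.inf
    em = EnrichedModel(partial=partial, disc=DiscrepancyParams.from_vector(t))
    X0 = np.stack([sc.phi for sc in obs_c.scenarios])
    grid = np.concatenate([[0.0], obs_c.times])
    opts = CALIBRATION_SOLVER_OPTS if solver_opts is None else solver_opts
    try:
        Y = simulate_enriched_batch(em, X0, grid, opts)  # (n_phi, T+1, s)
    except (SolverError, RuntimeError) as exc:
        logger.warning("enriched solve failed at theta=%s: %s", t, exc)
        return -np.inf
    pred = Y[:, 1:, :].transpose(2, 1, 0)  # (s, T, n_phi)
    resid = obs_c.values - pred
    n = resid.size
    sig2 = obs_c.sigma_eps_sq
    return -0.5 * n * np.log(2 * np.pi * sig2) - 0.5 * np.sum(resid**2) / sig2


def log_posterior(
    theta,
    obs_c: ObservationSet,
    partial: GLVModel,
    solver_opts: Mapping[str, Any] | None = None,
) -> float:
    lp = log_prior(theta)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(theta, obs_c, partial, solver_opts)


def _gauss_logq(y: np.ndarray, center: np.ndarray, cho) -> float:
    """Log-density of N(center, C) at y, up to the shared normalizing
    constant (which cancels in DR acceptance ratios)."""
    d = y - center
    return -0.5 * d @ cho_solve(cho, d)


def dram_sample(
    log_target: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_iter: int,
    seed: int | None = None,
    prop_cov: np.ndarray | float = 0.01,
    adapt_start: int = 1000,
    adapt_interval: int = 50,
    dr_scale: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Delayed-rejection adaptive Metropolis on an arbitrary log-density.

    Stage 1 proposes from N(x, C_t); on rejection a second stage proposes
    from N(x, dr_scale^2 C_t) and is accepted with the DR ratio, which keeps
    the chain in detailed balance.  After ``adapt_start`` iterations C_t is
    refreshed every ``adapt_interval`` iterations to (2.38^2/d) * cov(chain)
    plus a small jitter.

    Returns (chain, log_target values, acceptance rate) over all n_iter
    iterations; burn-in handling is the caller's business.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    lp = float(log_target(x))
    if not np.isfinite(lp):
        raise ValueError(f"log-target is not finite at the starting point {x0}")

    C = np.eye(d) * prop_cov if np.isscalar(prop_cov) else np.asarray(prop_cov)
    L = np.linalg.cholesky(C)
    cho = cho_factor(C, lower=True)
    sd = 2.38**2 / d

    chain = np.empty((n_iter, d))
    logps = np.empty(n_iter)
    n_accept = 0

    # running moments for adaptation
    mean = x.copy()
    M2 = np.zeros((d, d))
    count = 1

    for it in range(n_iter):
        y1 = x + L @ rng.standard_normal(d)
        lp1 = float(log_target(y1))
        log_a1 = lp1 - lp
        if np.log(rng.random()) < log_a1:
            x, lp = y1, lp1
            n_accept += 1
        else:
            # second stage: smaller step, DR acceptance ratio
            y2 = x + dr_scale * (L @ rng.standard_normal(d))
            lp2 = float(log_target(y2))
            if np.isfinite(lp2):
                # alpha1 evaluated from y2 toward y1
                log_a1_rev = lp1 - lp2
                num = lp2 + _gauss_logq(y1, y2, cho) + _log1m_exp(log_a1_rev)
                den = lp + _gauss_logq(y1, x, cho) + _log1m_exp(log_a1)
                if np.log(rng.random()) < num - den:
                    x, lp = y2, lp2
                    n_accept += 1
        chain[it] = x
        logps[it] = lp

        # incremental mean / scatter update
        count += 1
        delta = x - mean
        mean += delta / count
        M2 += np.outer(delta, x - mean)

        if it >= adapt_start and (it - adapt_start) % adapt_interval == 0:
            cov = M2 / (count - 1)
            C = sd * cov + sd * 1e-10 * np.eye(d)
            try:
                L = np.linalg.cholesky(C)
                cho = cho_factor(C, lower=True)
            except np.linalg.LinAlgError:  # degenerate early history
                pass

    return chain, logps, n_accept / n_iter


def _log1m_exp(log_a: float) -> float:
    """log(1 - min(1, exp(log_a))), guarded for the DR ratio."""
    if log_a >= 0:
        return -np.inf
    return float(np.log1p(-np.exp(log_a)))


def run_mcmc(
    obs_c: ObservationSet,
    partial: GLVModel,
    n_iter: int = 50_000,
    burn_in: float = 0.5,
    prop_scale: float = 0.01,
    seed: int | None = None,
    start: np.ndarray | None = None,
    solver_opts: Mapping[str, Any] | None = None,
    adapt_start: int = 1000,
) -> PosteriorSamples:
    """Sample the discrepancy-parameter posterior given calibration data.

    ``prop_scale`` sets the initial (pre-adaptation) proposal covariance
    prop_scale * I.  The default start, all deltas at -0.1, is admissible for
    every model; an inadmissible custom start raises immediately.
    """
    s = obs_c.s
    if partial.S != s:
        raise ValueError("partial model dimension must match observations")
    theta0 = np.full(2 * s, -0.1) if start is None else np.asarray(start, float)

    def log_target(t: np.ndarray) -> float:
        return log_posterior(t, obs_c, partial, solver_opts)

    chain, logps, acc = dram_sample(
        log_target, theta0, n_iter, seed=seed, prop_cov=prop_scale,
        adapt_start=adapt_start,
    )
    keep = int(n_iter * burn_in)
    chain, logps = chain[keep:], logps[keep:]

    import arviz as az

    half = chain.shape[0] // 2
    split = np.stack([chain[:half], chain[half: 2 * half]])  # (2, n/2, d)
    ess = np.array([float(az.ess(split[:, :, j])) for j in range(chain.shape[1])])
    rhat = np.array([float(az.rhat(split[:, :, j])) for j in range(chain.shape[1])])

    return PosteriorSamples(chain=chain, log_post=logps, acceptance_rate=acc,
                            seed=seed, ess=ess, rhat=rhat)
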
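"""Bayesian calibration: heteroscedastic likelihood, differential-evolution
MCMC, convergence diagnostics, MAP extraction and predictive intervals.

The error between observed and modelled transpiration is zero-mean normal
with a standard deviation that grows with the modelled rate: semi-log-linear
``SD = exp(alpha + beta_w1 E)`` for the W1 trees and proportional
``SD = beta_w2 E`` for the W2 trees.  Priors are independent uniform boxes,
so the log-posterior is the log-likelihood inside the box and -inf outside.
Sampling uses an ensemble of walkers with differential-evolution and
snooker proposals; only the second halves of the chains are retained for
the Gelman-Rubin diagnostic, the MAP and all downstream summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import emcee
import numpy as np
import pandas as pd

from .config import RunConfig
from .forward import Dataset, simulate
from .params import ParameterSpace

logger = logging.getLogger(__name__)

#: Floor on the error SD (mol H2O m-2 leaf s-1); keeps the proportional
#: error density proper when the modelled rate reaches zero.
SD_FLOOR = 1e-8

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def residuals(e_obs, e_model):
    """Observation-minus-model error, elementwise; the observation side is
    sap flow already converted to leaf area (J / rho)."""
    return np.asarray(e_obs, dtype=float) - np.asarray(e_model, dtype=float)


def error_sd(e_model, alpha: float, beta_w1: float, beta_w2: float,
             w1: np.ndarray) -> np.ndarray:
    """Heteroscedastic error SD per tree-day, floored at ``SD_FLOOR``."""
    e_model = np.asarray(e_model, dtype=float)
    w1col = np.asarray(w1, dtype=bool)[:, None]
    sd = np.where(w1col, np.exp(alpha + beta_w1 * e_model), beta_w2 * e_model)
    return np.maximum(sd, SD_FLOOR)


def log_likelihood(eps, e_model, alpha: float, beta_w1: float,
                   beta_w2: float, w1) -> float:
    """Sum of normal log-densities of the residuals under the group-wise
    heteroscedastic SD model.  Tree-days with NaN residual (missing
    observations) are excluded."""
    eps = np.asarray(eps, dtype=float)
    sd = error_sd(e_model, alpha, beta_w1, beta_w2, w1)
    mask = np.isfinite(eps)
    z = eps[mask] / sd[mask]
    return float(np.sum(-0.5 * z * z - np.log(sd[mask]) - _LOG_SQRT_2PI))


def make_log_posterior(ds: Dataset, space: ParameterSpace,
                       variant: str | None = None, rm2_cap: str = "none"):
    """Closure mapping a raw parameter vector to its log-posterior.

    Uniform priors contribute only the box indicator, so inside the box the
    value is the log-likelihood (flat-prior identity).  ``variant``
    overrides the space's layout variant (used for the plateau-capped RM2,
    which shares the FM layout).
    """
    if ds.e_obs is None:
        raise ValueError("dataset carries no observations")

    def log_posterior(vector) -> float:
        v = np.asarray(vector, dtype=float)
        if not space.in_box(v):
            return -np.inf
        dp = space.decode(v)
        sim = simulate(ds, dp, variant=variant, rm2_cap=rm2_cap)
        eps = ds.e_obs - sim.e_model
        return log_likelihood(eps, sim.e_model, dp.alpha, dp.beta_w1,
                              dp.beta_w2, ds.w1)

    return log_posterior


@dataclass
class PosteriorChain:
    """Raw walker trajectories plus the retained-half bookkeeping."""

    draws: np.ndarray        # (n_steps, n_walkers, ndim)
    log_prob: np.ndarray     # (n_steps, n_walkers)
    space: ParameterSpace
    seed: int
    acceptance: float

    @property
    def n_steps(self) -> int:
        return self.draws.shape[0]

    @property
    def retained(self) -> np.ndarray:
        """Second halves of the chains, shape (n_walkers, n_kept, ndim)."""
        half = self.n_steps // 2
        return np.swapaxes(self.draws[half:], 0, 1)

    @property
    def retained_log_prob(self) -> np.ndarray:
        half = self.n_steps // 2
        return np.swapaxes(self.log_prob[half:], 0, 1)

    @property
    def flat(self) -> np.ndarray:
        """Retained draws flattened to (n_walkers * n_kept, ndim)."""
        r = self.retained
        return r.reshape(-1, r.shape[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.flat, columns=self.space.names)
        df["log_posterior"] = self.retained_log_prob.reshape(-1)
        return df


def run_mcmc(log_prob, space: ParameterSpace, n_walkers: int = 48,
             n_steps: int = 3000, seed: int = 0, init: np.ndarray | None = None,
             progress: bool = False) -> PosteriorChain:
    """Sample the posterior with a differential-evolution ensemble.

    Walkers start from independent prior draws (or ``init``).  Proposals mix
    differential-evolution with snooker updates, the combination suited to
    the correlated, box-bounded posteriors of process models.  Fully
    reproducible from ``seed``.  Raises if the whole ensemble stagnates
    (mean acceptance below 1%).
    """
    if n_walkers < 3:
        raise ValueError("need at least 3 walkers")
    if n_walkers < 2 * space.ndim:
        logger.warning("fewer walkers (%d) than 2*ndim (%d); mixing may be slow",
                       n_walkers, 2 * space.ndim)
    rng = np.random.default_rng(seed)
    if init is None:
        init = space.sample_prior(rng, n_walkers)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, space.ndim, log_prob, moves=moves)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(init, n_steps, progress=progress)
    acc = float(np.mean(sampler.acceptance_fraction))
    if acc < 0.01:
        raise RuntimeError(
            f"sampler stagnated: mean acceptance {acc:.3%} < 1% — "
            "check priors/likelihood scaling or initial dispersion")
    return PosteriorChain(draws=sampler.get_chain(), log_prob=sampler.get_log_prob(),
                          space=space, seed=seed, acceptance=acc)


def gelman_rubin(chains) -> np.ndarray:
    """Gelman-Rubin potential scale reduction factor per parameter.

    ``chains`` has shape (n_chains, n_samples, ndim).  R-hat is
    ``sqrt(((n-1)/n W + B/n) / W)`` with W the mean within-chain variance
    and B/n the between-chain variance of the means.  Degenerate parameters
    with zero within-chain variance report 1.0.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 3 or chains.shape[0] < 2:
        raise ValueError("need (n_chains >= 2, n_samples, ndim)")
    n = chains.shape[1]
    w = np.mean(np.var(chains, axis=1, ddof=1), axis=0)
    b_over_n = np.var(np.mean(chains, axis=1), axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    return np.where(w > 0, rhat, 1.0)


def map_estimate(chain: PosteriorChain) -> np.ndarray:
    """Retained draw with the highest log-posterior (first occurrence on
    ties)."""
    lp = chain.retained_log_prob.reshape(-1)
    if lp.size == 0:
        raise ValueError("empty retained chain")
    return chain.flat[int(np.argmax(lp))].copy()


def predictive_interval(chain: PosteriorChain, ds: Dataset,
                        n_samples: int = 6000, seed: int = 0,
                        rm2_cap: str = "none"):
    """Pointwise 95% predictive band per tree-day.

    Draws ``n_samples`` parameter vectors from the retained posterior (with
    replacement), simulates each, adds one heteroscedastic error draw per
    tree-day, and returns the 2.5%/97.5% quantiles as an array of shape
    (2, n_trees, n_days).
    """
    rng = np.random.default_rng(seed)
    flat = chain.flat
    idx = rng.integers(0, flat.shape[0], size=n_samples)
    space = chain.space
    out = np.empty((n_samples, ds.n_trees, ds.n_days), dtype=np.float32)
    for k, j in enumerate(idx):
        dp = space.decode(flat[j])
        sim = simulate(ds, dp, rm2_cap=rm2_cap)
        sd = error_sd(sim.e_model, dp.alpha, dp.beta_w1, dp.beta_w2, ds.w1)
        out[k] = sim.e_model + rng.standard_normal(sim.e_model.shape) * sd
    return np.quantile(out.astype(float), [0.025, 0.975], axis=0)


@dataclass
class FitResult:
    """Calibration summary: MAP vector, marginal 95% credible intervals,
    R-hat per parameter and the full retained chain."""

    space: ParameterSpace
    chain: PosteriorChain
    map_vector: np.ndarray
    q_low: np.ndarray
    q_high: np.ndarray
    rhat: np.ndarray
    converged: bool

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.space.names,
            "MAP": self.map_vector,
            "q2.5": self.q_low,
            "q97.5": self.q_high,
            "rhat": self.rhat,
        })


def fit(ds: Dataset, variant: str = "FM", priors: dict | None = None,
        config: RunConfig | None = None, n_walkers: int | None = None,
        n_steps: int | None = None, seed: int | None = None,
        rm2_cap: str | None = None, progress: bool = False) -> FitResult:
    """Calibrate one model variant on a dataset and summarize the posterior.

    Non-convergence (any R-hat >= 1.1) is flagged on the result, never
    silently accepted.
    """
    config = config or ds.config
    inf = config.inference
    n_walkers = n_walkers or inf.n_walkers
    n_steps = n_steps or inf.n_steps
    seed = inf.seed if seed is None else seed
    rm2_cap = inf.rm2_cap if rm2_cap is None else rm2_cap
    layout = "FM" if (variant == "RM2" and rm2_cap == "ksr_star") else variant
    space = ParameterSpace(layout, n_trees=ds.n_trees, priors=priors,
                           config=config)
    log_post = make_log_posterior(ds, space, variant=variant, rm2_cap=rm2_cap)
    logger.info("running MCMC: variant=%s ndim=%d walkers=%d steps=%d seed=%d",
                variant, space.ndim, n_walkers, n_steps, seed)
    chain = run_mcmc(log_post, space, n_walkers=n_walkers, n_steps=n_steps,
                     seed=seed, progress=progress)
    flat = chain.flat
    q_low, q_high = np.quantile(flat, [0.025, 0.975], axis=0)
    rhat = gelman_rubin(chain.retained)
    converged = bool(np.all(rhat < 1.1))
    if not converged:
        logger.warning("convergence not reached: max R-hat = %.3f", rhat.max())
    return FitResult(space=space, chain=chain, map_vector=map_estimate(chain),
                     q_low=q_low, q_high=q_high, rhat=rhat, converged=converged)
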
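"""Posterior sampling and summaries for the marginalized CJS model.

The sampler is an adaptive blocked random-walk Metropolis on the
coefficient vector.  During burn-in the proposal covariance is adapted
Haario-style (empirical covariance of the chain history, scaled by a
Robbins-Monro-tuned factor targeting ~30% acceptance); adaptation is frozen
at the end of burn-in so the kept draws satisfy detailed balance.  Chains
are independent given distinct per-chain seeds (base_seed + chain index),
and a fixed configuration and seed reproduce the draws bit-exactly.

The study's chain settings — three chains of 10,000 iterations, 1,000
burn-in, thinning every 100, keeping 90 draws per chain — are available as
``MCMCConfig.study_settings()``.  The default configuration runs longer
with lighter thinning for more stable summaries; both are configuration
choices, not code paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("resight")

_TARGET_ACCEPT = 0.30
_STALL_WINDOW = 500  # zero acceptances over this many iterations -> error


@dataclass
class MCMCConfig:
    """Chain settings.

    ``thin`` and ``burn_in`` bookkeeping keeps exactly
    ``floor((n_iter - burn_in) / thin)`` draws per chain.
    """

    n_chains: int = 3
    n_iter: int = 50_000
    burn_in: int = 5_000
    thin: int = 10
    base_seed: int = 0
    adapt: bool = True
    proposal_scales: np.ndarray | float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def study_settings(cls, base_seed: int = 0) -> "MCMCConfig":
        """Three chains x 10,000 iterations, 1,000 burn-in, thin 100."""
        return cls(n_chains=3, n_iter=10_000, burn_in=1_000, thin=100,
                   base_seed=base_seed)

    def with_seed(self, base_seed: int) -> "MCMCConfig":
        return replace(self, base_seed=base_seed)


@dataclass
class PosteriorSamples:
    """Kept MCMC draws: array of shape (chains, kept iterations, parameters)."""

    draws: np.ndarray
    parameter_names: list[str]
    config: MCMCConfig
    accept_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, iterations, parameters)")
        if self.draws.shape[2] != len(self.parameter_names):
            raise ValueError("parameter_names length mismatch")
        if not np.isfinite(self.draws).all():
            raise ValueError("non-finite draws")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def flat(self) -> np.ndarray:
        """All chains pooled: (chains * kept, parameters)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def column(self, parameter: str | int) -> int:
        if isinstance(parameter, int):
            return parameter
        return self.parameter_names.index(parameter)

    def to_dataframe(self) -> pd.DataFrame:
        c, k, _ = self.draws.shape
        df = pd.DataFrame(self.flat(), columns=self.parameter_names)
        df.insert(0, "iteration", np.tile(np.arange(k), c))
        df.insert(0, "chain", np.repeat(np.arange(c), k))
        return df

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def _run_chain(
    logpost: Callable[[np.ndarray], float],
    x0: np.ndarray,
    config: MCMCConfig,
    seed: int,
) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng(seed)
    k = x0.size
    scales = np.broadcast_to(
        np.asarray(config.proposal_scales, dtype=float), (k,)
    ).copy()
    cov = np.diag(scales**2)
    chol = np.linalg.cholesky(cov)
    log_lambda = 0.0

    x = x0.copy()
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("log_posterior is not finite at the initial point")

    kept = np.empty((config.n_kept, k))
    kept_i = 0
    n_acc = 0
    window_acc = 0

    # running moments for Haario covariance adaptation (burn-in only)
    mean = x.copy()
    m2 = np.zeros((k, k))
    count = 1

    for it in range(1, config.n_iter + 1):
        step = np.exp(log_lambda) * (chol @ rng.standard_normal(k))
        prop = x + step
        lp_prop = logpost(prop)
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            x = prop
            lp = lp_prop
            n_acc += 1
            window_acc += 1

        in_burn = it <= config.burn_in
        if in_burn and config.adapt:
            # Robbins-Monro on the global scale toward the target rate
            gamma = (it + 10) ** -0.6
            log_lambda += gamma * ((1.0 if accept else 0.0) - _TARGET_ACCEPT)
            # running empirical covariance of the chain history
            count += 1
            delta = x - mean
            mean += delta / count
            m2 += np.outer(delta, x - mean)
            if count > 10 * k and it % 100 == 0:
                emp = m2 / (count - 1) + 1e-9 * np.eye(k)
                try:
                    chol = np.linalg.cholesky(emp)
                except np.linalg.LinAlgError:
                    pass

        if it % _STALL_WINDOW == 0:
            if window_acc == 0:
                raise RuntimeError(
                    f"zero acceptances over {_STALL_WINDOW} iterations: "
                    "proposal scales are mis-matched to the posterior"
                )
            window_acc = 0

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            kept[kept_i] = x
            kept_i += 1

    assert kept_i == config.n_kept
    return kept, n_acc / config.n_iter


def run_mcmc(
    log_posterior: Callable[[np.ndarray], float],
    n_params: int,
    config: MCMCConfig,
    parameter_names: list[str] | None = None,
    init: np.ndarray | None = None,
) -> PosteriorSamples:
    """Sample the posterior with independent adaptive Metropolis chains.

    Coefficients start at 0 (the prior mean) unless ``init`` is given.
    Chain c uses seed ``base_seed + c``; identical config and seed give
    bit-identical draws.  Raises if the posterior is non-finite at the
    start, or if a chain stalls (zero acceptance over an adaptation
    window).
    """
    names = parameter_names or [f"theta{i}" for i in range(n_params)]
    x0 = np.zeros(n_params) if init is None else np.asarray(init, dtype=float)
    if x0.shape != (n_params,):
        raise ValueError("init has wrong length")

    draws = np.empty((config.n_chains, config.n_kept, n_params))
    rates = np.empty(config.n_chains)
    for c in range(config.n_chains):
        draws[c], rates[c] = _run_chain(
            log_posterior, x0, config, seed=config.base_seed + c
        )
        logger.info("chain %d: acceptance rate %.3f", c, rates[c])
    return PosteriorSamples(draws, names, config, accept_rates=rates)


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

def _split_chains(x: np.ndarray) -> np.ndarray:
    """Split each chain in half, (chains, iters) -> (2*chains, iters//2)."""
    c, n = x.shape
    half = n // 2
    return np.concatenate([x[:, :half], x[:, n - half:]], axis=0)


def gelman_rubin(samples: PosteriorSamples | np.ndarray,
                 parameter: str | int | None = None) -> float:
    """Split-chain potential scale reduction factor (Rhat).

    Each chain is halved, then Rhat = sqrt(((n-1)/n * W + B/n) / W) with W
    the mean within-chain variance and B the between-chain variance of the
    means.  Approaches 1 at convergence.  Raises on degenerate input (zero
    within-chain variance), rather than silently reporting 1.
    """
    if isinstance(samples, PosteriorSamples):
        if parameter is None:
            raise ValueError("specify a parameter")
        x = samples.draws[:, :, samples.column(parameter)]
    else:
        x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    x = _split_chains(x)
    m, n = x.shape
    W = float(x.var(axis=1, ddof=1).mean())
    if W == 0.0 or bool(np.all(x == x[:, :1])):
        raise ValueError("zero within-chain variance: Rhat undefined")
    B_over_n = float(x.mean(axis=1).var(ddof=1))
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


@dataclass
class PosteriorSummary:
    """Posterior mean, SD, equal-tailed 95% credible interval and Rhat per
    parameter and per derived quantity, as a DataFrame."""

    table: pd.DataFrame

    def row(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def ci_width(self, name: str) -> float:
        r = self.table.loc[name]
        return float(r["uci"] - r["lci"])

    def to_json(self, path: str | Path | None = None) -> str:
        text = self.table.to_json(orient="index", indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def summarize(
    samples: PosteriorSamples,
    derived: Mapping[str, Callable[[np.ndarray], float]] | None = None,
) -> PosteriorSummary:
    """Summarize draws: mean, SD, 2.5%/97.5% quantiles, split-Rhat.

    ``derived`` maps a name to a transform applied to each draw vector
    (e.g. the population-average survival probability); derived quantities
    are computed per draw, preserving chain structure for their Rhat.
    """
    if samples.n_kept == 0:
        raise ValueError("no draws to summarize")
    c, k, npar = samples.draws.shape
    columns: dict[str, np.ndarray] = {
        name: samples.draws[:, :, j] for j, name in enumerate(samples.parameter_names)
    }
    for name, fn in (derived or {}).items():
        vals = np.array(
            [[fn(samples.draws[ci, ki]) for ki in range(k)] for ci in range(c)]
        )
        columns[name] = vals

    rows = []
    for name, x in columns.items():
        pooled = x.reshape(-1)
        try:
            rhat = gelman_rubin(x)
        except ValueError:
            rhat = np.nan
        rows.append(
            {
                "parameter": name,
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
                "lci": float(np.quantile(pooled, 0.025)),
                "uci": float(np.quantile(pooled, 0.975)),
                "rhat": rhat,
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    return PosteriorSummary(table)
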
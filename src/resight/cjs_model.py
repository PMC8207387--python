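"""Individual state-space Cormack-Jolly-Seber likelihood with covariates.

The model separates the demographic process from its observation.  For
individual i first captured at occasion e_i, the latent alive state X_{i,t}
and the detection Y_{i,t} follow, for t >= e_i,

    Y_{i,t}   | X_{i,t} ~ Bernoulli(X_{i,t} * p_{i,t})      (observation)
    X_{i,t+1} | X_{i,t} ~ Bernoulli(X_{i,t} * phi_{i,t})    (state)

with p_{i,e_i} = 1 (the model conditions on first capture, which therefore
contributes no detection term).  phi_{i,t} is apparent survival from
occasion t to t+1 — mortality and permanent emigration are confounded — and
p_{i,t} is the resighting probability at occasion t.  Both get logit-linear
submodels: survival may depend on sex, age (days since marking) and wing
length; resighting on sex.

Rather than sampling the latent states, the likelihood is marginalized in
closed form with the chi recursion, where chi_{i,t} is the probability that
an individual alive at occasion t is never seen again:

    chi_{i,T} = 1
    chi_{i,t} = (1 - phi_{i,t}) + phi_{i,t} (1 - p_{i,t+1}) chi_{i,t+1}

The complete-data form is retained for the simulator and for exhaustive
enumeration oracles in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import expit as _expit
from scipy.stats import norm

from .capture_data import CaptureHistory, CovariateTable

PHI_TERMS = ("intercept", "sex", "age", "wing_length")
P_TERMS = ("intercept", "sex")


# ---------------------------------------------------------------------------
# Link functions
# ---------------------------------------------------------------------------

def logit(x):
    """Log-odds.  Defined only on the open interval (0, 1)."""
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("logit requires 0 < x < 1")
    return np.log(x) - np.log1p(-x)


def inv_logit(x):
    """Inverse logit (logistic function), monotone and bounded in (0, 1)."""
    return _expit(x)


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Covariate terms for the two logit-linear predictors.

    ``phi_terms`` (survival) may draw from {intercept, sex, age,
    wing_length}; ``p_terms`` (resighting) from {intercept, sex}.  The
    intercept is mandatory in both.  ``standardization`` maps a term to the
    (mean, sd) used for z-scoring; terms absent from the map enter raw.
    Sex is coded as an indicator (male = 1, female = 0) and is never
    standardized.  Age is defined as t - e_i, days since marking.
    """

    phi_terms: tuple[str, ...] = ("intercept",)
    p_terms: tuple[str, ...] = ("intercept",)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi_terms = tuple(self.phi_terms)
        self.p_terms = tuple(self.p_terms)
        if "intercept" not in self.phi_terms or "intercept" not in self.p_terms:
            raise ValueError("intercept must be present in both term lists")
        bad = set(self.phi_terms) - set(PHI_TERMS)
        if bad:
            raise ValueError(f"unknown phi terms: {sorted(bad)}")
        bad = set(self.p_terms) - set(P_TERMS)
        if bad:
            raise ValueError(f"unknown p terms: {sorted(bad)}")
        if len(set(self.phi_terms)) != len(self.phi_terms) or len(
            set(self.p_terms)
        ) != len(self.p_terms):
            raise ValueError("duplicate terms")

    @property
    def n_params(self) -> int:
        return len(self.phi_terms) + len(self.p_terms)

    @property
    def parameter_names(self) -> list[str]:
        return [f"phi.{t}" for t in self.phi_terms] + [f"p.{t}" for t in self.p_terms]

    @classmethod
    def from_data(
        cls,
        phi_terms: Sequence[str],
        p_terms: Sequence[str],
        covs: CovariateTable,
        e: np.ndarray,
        T: int,
    ) -> "ModelSpec":
        """Build a spec with z-scoring constants taken from the data.

        Wing length is standardized over individuals; age over the in-study
        (i, t) cells e_i <= t <= T-1 of the marked population.
        """
        std: dict[str, tuple[float, float]] = {}
        if "wing_length" in phi_terms:
            wl = covs.table["wing_length"].to_numpy(dtype=float)
            if np.isnan(wl).any():
                raise ValueError(
                    "missing wing_length; impute or drop before standardizing"
                )
            sd = float(wl.std(ddof=0))
            std["wing_length"] = (float(wl.mean()), sd if sd > 0 else 1.0)
        if "age" in phi_terms:
            ages = np.concatenate(
                [np.arange(0, T - int(ei)) for ei in e if int(ei) < T]
            ).astype(float)
            sd = float(ages.std(ddof=0)) if ages.size else 1.0
            std["age"] = (float(ages.mean()) if ages.size else 0.0, sd if sd > 0 else 1.0)
        return cls(tuple(phi_terms), tuple(p_terms), std)


@dataclass
class Priors:
    """Independent normal priors on every coefficient, parameterized by
    precision as in BUGS/JAGS: mean 0, precision 0.01 means SD 10 (a flat,
    noninformative choice on the logit scale)."""

    mean: float = 0.0
    precision: float = 0.01

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise ValueError("precision must be > 0")

    @property
    def sd(self) -> float:
        return 1.0 / np.sqrt(self.precision)


@dataclass
class ParameterVector:
    """Coefficients for the survival (phi) and resighting (p) predictors,
    both on the logit scale, ordered as in ``ModelSpec``."""

    beta_phi: np.ndarray
    beta_p: np.ndarray

    def __post_init__(self) -> None:
        self.beta_phi = np.atleast_1d(np.asarray(self.beta_phi, dtype=float))
        self.beta_p = np.atleast_1d(np.asarray(self.beta_p, dtype=float))
        if not (np.isfinite(self.beta_phi).all() and np.isfinite(self.beta_p).all()):
            raise ValueError("coefficients must be finite")

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.beta_phi, self.beta_p])

    @classmethod
    def from_flat(cls, x: np.ndarray, spec: ModelSpec) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        k = len(spec.phi_terms)
        if x.shape != (spec.n_params,):
            raise ValueError(f"expected {spec.n_params} coefficients, got {x.shape}")
        return cls(beta_phi=x[:k], beta_p=x[k:])


# ---------------------------------------------------------------------------
# Design construction and linear predictors
# ---------------------------------------------------------------------------

def _term_matrix(
    term: str,
    spec: ModelSpec,
    covs: CovariateTable,
    e: np.ndarray,
    n_cols: int,
    time_varying_age: bool,
) -> np.ndarray:
    n = len(covs.table)
    if term == "intercept":
        return np.ones((n, n_cols))
    if term == "sex":
        male = (covs.table["sex"].to_numpy() == "M").astype(float)
        return np.repeat(male[:, None], n_cols, axis=1)
    if term == "wing_length":
        wl = covs.table["wing_length"].to_numpy(dtype=float)
        if np.isnan(wl).any():
            missing = covs.table.loc[np.isnan(wl), "individual_id"].tolist()
            raise ValueError(f"missing wing_length for individuals: {missing}")
        if term in spec.standardization:
            m, s = spec.standardization[term]
            wl = (wl - m) / s
        return np.repeat(wl[:, None], n_cols, axis=1)
    if term == "age":
        # age at occasion t is t - e_i; the phi column j covers the interval
        # starting at occasion t = j + 1
        t_idx = np.arange(1, n_cols + 1)[None, :]
        ages = t_idx - np.asarray(e, dtype=float)[:, None]
        if term in spec.standardization:
            m, s = spec.standardization[term]
            ages = (ages - m) / s
        return ages
    raise ValueError(f"unknown term {term!r}")


def design_matrices(
    spec: ModelSpec, covs: CovariateTable, e: np.ndarray, T: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked design arrays: (k_phi, n, T-1) for survival and (k_p, n, T)
    for resighting."""
    X_phi = np.stack(
        [_term_matrix(t, spec, covs, e, T - 1, True) for t in spec.phi_terms]
    )
    X_p = np.stack([_term_matrix(t, spec, covs, e, T, False) for t in spec.p_terms])
    return X_phi, X_p


def linear_predictors(
    params: ParameterVector,
    spec: ModelSpec,
    covs: CovariateTable,
    e: np.ndarray,
    T: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual probabilities: phi (n x T-1) and p (n x T), in (0, 1).

    phi[i, j] is survival over the interval starting at occasion j+1;
    p[i, j] is the resighting probability at occasion j+1 (the column at
    e_i is present but unused by the likelihood, which fixes p_{i,e_i}=1).
    """
    if len(params.beta_phi) != len(spec.phi_terms) or len(params.beta_p) != len(
        spec.p_terms
    ):
        raise ValueError("parameter length does not match spec")
    X_phi, X_p = design_matrices(spec, covs, e, T)
    phi = inv_logit(np.tensordot(params.beta_phi, X_phi, axes=1))
    p = inv_logit(np.tensordot(params.beta_p, X_p, axes=1))
    return phi, p


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _check_latent(X: np.ndarray, e: np.ndarray) -> None:
    n, T = X.shape
    cols = np.arange(1, T + 1)
    active = cols[None, :] >= e[:, None]
    if not np.isin(X[active], (0, 1)).all():
        raise ValueError("latent states must be 0/1")
    if np.any(X[np.arange(n), e - 1] != 1):
        raise ValueError("X must be 1 at first capture (alive when marked)")
    # death is absorbing: no 0 -> 1 transition once in the study
    inc = (np.diff(X, axis=1) > 0) & (cols[None, :-1] >= e[:, None])
    if inc.any():
        raise ValueError("X violates the absorbing-death invariant")


def complete_data_loglik(
    Y: np.ndarray,
    X: np.ndarray,
    phi: np.ndarray,
    p: np.ndarray,
    e: np.ndarray,
) -> float:
    """Joint log-likelihood of detections and latent alive states.

    Sums the Bernoulli observation terms (t > e_i; first capture has
    p_{i,e_i}=1 and contributes nothing) and the Bernoulli state-transition
    terms (t = e_i..T-1).  Returns ``-inf`` for impossible pairs (a
    detection while dead); raises if X itself is inadmissible.
    """
    Y = np.asarray(Y)
    X = np.asarray(X)
    e = np.asarray(e, dtype=np.int64)
    n, T = Y.shape
    _check_latent(X, e)
    if np.any((Y == 1) & (X == 0) & (np.arange(1, T + 1)[None, :] >= e[:, None])):
        return -np.inf

    cols = np.arange(1, T + 1)
    with np.errstate(divide="ignore"):
        # observation terms: t > e_i, success prob X_t * p_t
        obs_mask = cols[None, :] > e[:, None]
        prob = X * p
        obs = np.where(Y == 1, np.log(prob), np.log1p(-prob))
        total = float(np.where(obs_mask, obs, 0.0).sum())
        # state terms: t = e_i..T-1, success prob X_t * phi_t
        st_mask = cols[None, : T - 1] >= e[:, None]
        sp = X[:, :-1] * phi
        st = np.where(X[:, 1:] == 1, np.log(sp), np.log1p(-sp))
        total += float(np.where(st_mask, st, 0.0).sum())
    return total


def chi_probabilities(phi: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Never-seen-again probabilities, (n x T).

    chi[i, t-1] is the probability an individual alive at occasion t is not
    detected at any occasion after t.  Backward recursion from chi_{i,T}=1.
    """
    n, T = p.shape
    chi = np.ones((n, T))
    for j in range(T - 2, -1, -1):
        chi[:, j] = (1.0 - phi[:, j]) + phi[:, j] * (1.0 - p[:, j + 1]) * chi[:, j + 1]
    return chi


def marginal_loglik(
    Y: np.ndarray, phi: np.ndarray, p: np.ndarray, e: np.ndarray
) -> float:
    """CJS log-likelihood with latent states summed out (chi recursion).

    Per individual: survival and detection/non-detection terms over the
    occasions between first and last detection, times the probability
    chi_{i,l_i} of never being seen after the last detection.  Equals the
    log-sum-exp of ``complete_data_loglik`` over all admissible latent
    sequences.
    """
    Y = np.asarray(Y)
    e = np.asarray(e, dtype=np.int64)
    n, T = Y.shape
    if phi.shape != (n, T - 1) or p.shape != (n, T):
        raise ValueError("phi must be n x (T-1) and p n x T")
    occ = np.arange(1, T + 1)
    if np.any(Y[np.arange(n), e - 1] != 1) or np.any(
        (Y == 1) & (occ[None, :] < e[:, None])
    ):
        raise ValueError("invalid capture history: check Y against e")

    last = (Y * occ).max(axis=1)  # l_i, 1-based

    with np.errstate(divide="ignore"):
        # columns j = 0..T-2 cover the interval starting at occasion t = j+1;
        # active when e_i <= t <= l_i - 1
        j_occ = occ[: T - 1][None, :]
        active = (j_occ >= e[:, None]) & (j_occ <= (last - 1)[:, None])
        det = np.where(Y[:, 1:] == 1, np.log(p[:, 1:]), np.log1p(-p[:, 1:]))
        contrib = np.log(phi) + det
        total = float(np.where(active, contrib, 0.0).sum())
        chi = chi_probabilities(phi, p)
        total += float(np.log(chi[np.arange(n), last - 1]).sum())
    return total


# ---------------------------------------------------------------------------
# Prior and posterior
# ---------------------------------------------------------------------------

def log_prior(params: ParameterVector, priors: Priors | None = None) -> float:
    """Sum of independent normal log-densities over all coefficients."""
    priors = priors or Priors()
    flat = params.flatten()
    return float(norm.logpdf(flat, loc=priors.mean, scale=priors.sd).sum())


def log_posterior(
    params: ParameterVector,
    spec: ModelSpec,
    history: CaptureHistory,
    covs: CovariateTable,
    priors: Priors | None = None,
) -> float:
    """Unnormalized log-posterior: marginal likelihood plus prior."""
    phi, p = linear_predictors(params, spec, covs, history.e, history.T)
    return marginal_loglik(history.Y, phi, p, history.e) + log_prior(params, priors)


def derived_probability_transforms(
    spec: ModelSpec,
    history: CaptureHistory,
    covs: CovariateTable,
    kind: str = "population_average",
) -> dict[str, Callable[[np.ndarray], float]]:
    """Per-draw transforms for the average survival and resighting
    probability, keyed ``avg_survival_prob`` / ``avg_resight_prob``.

    ``population_average`` (default): the mean of inv_logit over every
    individual's linear predictor, taken over in-study cells (occasions
    e_i..T-1 for survival, occasions after e_i for resighting).
    ``reference_level``: inv_logit of the intercept alone (a female with
    covariates at their standardized zero).
    """
    covs = covs.aligned_to(history)
    X_phi, X_p = design_matrices(spec, covs, history.e, history.T)
    occ = np.arange(1, history.T + 1)
    phi_cells = occ[: history.T - 1][None, :] >= history.e[:, None]
    p_cells = occ[None, :] > history.e[:, None]
    k_phi = len(spec.phi_terms)

    if kind == "population_average":
        return {
            "avg_survival_prob": lambda x: float(
                _expit(np.tensordot(x[:k_phi], X_phi, axes=1))[phi_cells].mean()
            ),
            "avg_resight_prob": lambda x: float(
                _expit(np.tensordot(x[k_phi:], X_p, axes=1))[p_cells].mean()
            ),
        }
    if kind == "reference_level":
        return {
            "avg_survival_prob": lambda x: float(_expit(x[0])),
            "avg_resight_prob": lambda x: float(_expit(x[k_phi])),
        }
    raise ValueError(f"unknown kind {kind!r}")


def make_log_posterior(
    spec: ModelSpec,
    history: CaptureHistory,
    covs: CovariateTable,
    priors: Priors | None = None,
) -> Callable[[np.ndarray], float]:
    """Compile the log-posterior into a fast closure over a flat coefficient
    vector (design matrices and masks precomputed once, for MCMC)."""
    priors = priors or Priors()
    covs = covs.aligned_to(history)
    X_phi, X_p = design_matrices(spec, covs, history.e, history.T)
    Y = history.Y.astype(np.int8)
    e = history.e
    n, T = Y.shape
    occ = np.arange(1, T + 1)
    last = (Y * occ).max(axis=1)
    j_occ = occ[: T - 1][None, :]
    active = (j_occ >= e[:, None]) & (j_occ <= (last - 1)[:, None])
    y_after = Y[:, 1:] == 1
    rows = np.arange(n)
    k_phi = len(spec.phi_terms)
    prior_const = -0.5 * np.log(2 * np.pi * priors.sd**2)

    def logpost(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        phi = _expit(np.tensordot(x[:k_phi], X_phi, axes=1))
        p = _expit(np.tensordot(x[k_phi:], X_p, axes=1))
        with np.errstate(divide="ignore"):
            det = np.where(y_after, np.log(p[:, 1:]), np.log1p(-p[:, 1:]))
            total = float(np.where(active, np.log(phi) + det, 0.0).sum())
            chi = chi_probabilities(phi, p)
            total += float(np.log(chi[rows, last - 1]).sum())
        total += float(
            (prior_const - 0.5 * ((x - priors.mean) / priors.sd) ** 2).sum()
        )
        return total

    return logpost
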
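"""Independent reference computations used to check the CJS likelihood.

``enumerate_marginal`` sums the complete-data likelihood over every
admissible latent sequence (the latent state of a CJS individual is fully
determined by its death interval, so enumeration is over death times).
``brute_marginal_single`` recomputes the same quantity for one individual
from first principles — plain Bernoulli products, no package code — so the
two oracles are independent of the chi-recursion implementation and of
each other.
"""

import math

import numpy as np
from scipy.special import logsumexp

from resight import complete_data_loglik


def latent_from_death(e: int, d: int, T: int) -> np.ndarray:
    """Alive at occasions e..d, dead after (d = T means survived to the end)."""
    X = np.zeros((1, T), dtype=int)
    X[0, e - 1 : d] = 1
    return X


def enumerate_marginal(Y, phi, p, e) -> float:
    """Log-sum-exp of the complete-data log-likelihood over all admissible
    latent sequences, individual by individual."""
    Y = np.asarray(Y)
    n, T = Y.shape
    total = 0.0
    for i in range(n):
        terms = [
            complete_data_loglik(
                Y[i : i + 1],
                latent_from_death(int(e[i]), d, T),
                phi[i : i + 1],
                p[i : i + 1],
                np.array([e[i]]),
            )
            for d in range(int(e[i]), T + 1)
        ]
        total += logsumexp(terms)
    return float(total)


def brute_marginal_single(y, phi, p, e: int) -> float:
    """Likelihood of one capture history, from scratch.

    For each death time d: survive e..d (and die at d if d < T), and for
    every occasion t in (e, d] be detected iff y_t = 1; detection after d
    is impossible.  Pure python, no shared code with the implementation.
    """
    y = list(y)
    T = len(y)
    total = 0.0
    for d in range(e, T + 1):
        prob = 1.0
        for t in range(e, d):  # survive interval t -> t+1
            prob *= phi[t - 1]
        if d < T:  # die during interval d -> d+1
            prob *= 1.0 - phi[d - 1]
        for t in range(e + 1, T + 1):
            if t <= d:
                prob *= p[t - 1] if y[t - 1] else 1.0 - p[t - 1]
            elif y[t - 1]:
                prob = 0.0
        total += prob
    return math.log(total) if total > 0 else -math.inf


def all_single_histories(T: int, e: int):
    """Every valid capture history for one individual first caught at e."""
    free = T - e
    for bits in range(2**free):
        y = [0] * T
        y[e - 1] = 1
        for j in range(free):
            y[e + j] = (bits >> j) & 1
        yield y
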
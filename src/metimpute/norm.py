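"""Normal distribution model (NORM) imputation.

Each genotype-attribute vector across environments, x_ik (on the
column-standardized scale), is modelled as i.i.d. Normal(mu_ik,
sigma2_ik).  The common mean and variance are estimated either by
maximum likelihood or by a conjugate Gibbs sampler under Jeffreys'
noninformative prior f(mu, sigma2) = 1/sigma2, whose full conditionals
are

    sigma2 | mu ~ InverseGamma(n/2, n * V_mu / 2),  V_mu = mean((x - mu)^2)
    mu | sigma2 ~ Normal(xbar, sigma2 / n)

with n the number of observed environments for that vector.  Missing
entries are then drawn as mu_hat + z * sigma_hat with independent
standard-normal z, repeated over the H imputations.  A wholly missing
column poses no special case here: it contributes one missing entry to
each of the I vectors of its attribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .base import BaseMETImputer, spawn_rngs

__all__ = ["NormParams", "norm_mle", "norm_gibbs", "norm_impute", "NORMImputer"]


@dataclass
class NormParams:
    mu_hat: float
    sigma2_hat: float
    method: str
    n_obs: int
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_hat < 0:
            raise ValueError("sigma2_hat must be nonnegative")


def _observed(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    obs = x[np.isfinite(x)]
    if obs.size < 2:
        raise ValueError(f"need >= 2 observed entries, got {obs.size}")
    return obs


def norm_mle(x) -> NormParams:
    """Maximum-likelihood mean and variance of one environment vector.

    The variance uses the ML denominator 1/n (not 1/(n-1)), with n the
    observed count.
    """
    obs = _observed(x)
    mu = obs.mean()
    sigma2 = float(np.mean((obs - mu) ** 2))
    return NormParams(float(mu), sigma2, "mle", obs.size)


def norm_gibbs(x, n_samples: int = 5500, burn_in: int = 500, random_state=None) -> NormParams:
    """Posterior-mean estimates from the Jeffreys-prior Gibbs sampler."""
    if n_samples < 1 or burn_in >= n_samples:
        raise ValueError("need n_samples >= 1 and burn_in < n_samples")
    obs = _observed(x)
    rng = np.random.default_rng(random_state)
    mu_draws, s2_draws = _gibbs_chains(
        np.array([obs.sum()]),
        np.array([np.sum(obs**2)]),
        np.array([obs.size]),
        n_samples,
        rng,
    )
    mu = mu_draws[burn_in:].mean()
    s2 = s2_draws[burn_in:].mean()
    return NormParams(float(mu), float(s2), "gibbs", obs.size, n_samples)


def _gibbs_chains(sum_x, sum_x2, n, n_samples, rng):
    """Run M Jeffreys-prior chains in parallel (vectorized over vectors).

    Sufficient statistics per vector: sum, sum of squares, count.
    Returns (n_samples, M) draws of mu and sigma2.
    """
    sum_x = np.asarray(sum_x, dtype=float)
    sum_x2 = np.asarray(sum_x2, dtype=float)
    n = np.asarray(n, dtype=float)
    M = sum_x.size
    xbar = sum_x / n
    mu = xbar.copy()
    mu_out = np.empty((n_samples, M))
    s2_out = np.empty((n_samples, M))
    for t in range(n_samples):
        # V_mu = mean((x - mu)^2) from the sufficient statistics
        v_mu = (sum_x2 - 2 * mu * sum_x + n * mu**2) / n
        s2 = (n * v_mu / 2.0) / rng.gamma(n / 2.0, 1.0, size=M)
        mu = xbar + rng.standard_normal(M) * np.sqrt(s2 / n)
        s2_out[t] = s2
        mu_out[t] = mu
    return mu_out, s2_out


def norm_impute(params: NormParams, n_values: int, random_state=None) -> np.ndarray:
    """Draw imputations mu_hat + z * sigma_hat, independent z per entry."""
    rng = np.random.default_rng(random_state)
    return params.mu_hat + rng.standard_normal(n_values) * np.sqrt(params.sigma2_hat)


class NORMImputer(BaseMETImputer):
    """Normal-distribution-model imputer (Bayesian or ML fit).

    Parameters
    ----------
    method : {"mle", "gibbs"}
        "mle" (non-Bayesian) fits the mean/variance once; only the
        imputation noise varies between imputations.  "gibbs" (Bayesian)
        re-runs the conjugate sampler each imputation, propagating
        parameter uncertainty.
    n_imputations : int, default 100
    gibbs_samples, burn_in : chain length and discarded prefix.
    random_state : master seed.
    """

    def __init__(
        self,
        method: str = "mle",
        n_imputations: int = 100,
        gibbs_samples: int = 5500,
        burn_in: int = 500,
        random_state: int | None = None,
    ):
        self.method = method
        self.n_imputations = n_imputations
        self.gibbs_samples = gibbs_samples
        self.burn_in = burn_in
        self.random_state = random_state

    def _impute_all(self, std, pattern, missing, random_state):
        if self.method not in ("mle", "gibbs"):
            raise ValueError(f"method must be 'mle' or 'gibbs', got {self.method!r}")
        I, J, K = std.shape
        vecs = sorted({(i, k) for i, _, k in missing})
        vec_of = {v: m for m, v in enumerate(vecs)}
        slot = np.array([vec_of[(i, k)] for i, _, k in missing], dtype=int)
        sum_x = np.empty(len(vecs))
        sum_x2 = np.empty(len(vecs))
        n = np.empty(len(vecs), dtype=int)
        singletons = 0
        for m, (i, k) in enumerate(vecs):
            row = std.values[i, :, k]
            obs = row[np.isfinite(row)]
            if obs.size < 1:
                raise ValueError(
                    f"genotype {i}, attribute {k}: no observed environment"
                )
            singletons += obs.size == 1
            sum_x[m], sum_x2[m], n[m] = obs.sum(), np.sum(obs**2), obs.size
        if singletons:
            warnings.warn(
                f"{singletons} genotype-attribute vector(s) have a single "
                "observed environment; their imputations degenerate to that "
                "value with zero variance",
                stacklevel=2,
            )
        rngs = spawn_rngs(random_state, self.n_imputations)
        out = np.empty((self.n_imputations, len(missing)))
        if self.method == "mle":
            xbar = sum_x / n
            s2 = (sum_x2 - n * xbar**2) / n  # ML denominator
            s2 = np.maximum(s2, 0.0)
            for h, rng in enumerate(rngs):
                z = rng.standard_normal(len(missing))
                out[h] = xbar[slot] + z * np.sqrt(s2[slot])
        else:
            if not 0 <= self.burn_in < self.gibbs_samples:
                raise ValueError("need 0 <= burn_in < gibbs_samples")
            for h, rng in enumerate(rngs):
                mu_d, s2_d = _gibbs_chains(sum_x, sum_x2, n, self.gibbs_samples, rng)
                mu = mu_d[self.burn_in :].mean(axis=0)
                s2 = s2_d[self.burn_in :].mean(axis=0)
                z = rng.standard_normal(len(missing))
                out[h] = mu[slot] + z * np.sqrt(s2[slot])
        return out
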
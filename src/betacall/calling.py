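"""Per-individual probabilistic genotype calling from learned mixture
parameters.

For each site the posterior over genotypes g ∈ {0, 1, 2} is

    P(g | data) ∝ pi_g * (1/S) Σ_s BB(n_alt | n_total, mu_g^(s), kappa_g^(s)),

a Monte-Carlo average of the component likelihood over the S posterior draws
(full propagation of parameter uncertainty; a plug-in mode using posterior
means is available for speed).  The prior weights pi are either the
posterior-mean mixture weights learned during training (default) or
Hardy-Weinberg probabilities derived from a supplied effect allele frequency.

A hard call reports the most probable genotype only when its posterior
probability reaches a threshold (default 0.99); otherwise the site is left
missing.  The dosage Σ_g g·P(g) is always populated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core import AlleleCount, betabin_logpmf
from .inference import PosteriorDraws

__all__ = ["GenotypeCall", "genotype_posterior", "hard_call", "call_sample", "hwe_prior"]


@dataclass(frozen=True)
class GenotypeCall:
    """Posterior genotype call at one site.

    ``hard_call`` is 0/1/2 or ``None`` for missing (posterior maximum below
    the calling threshold).  ``dosage`` = probs[1] + 2*probs[2] ∈ [0, 2].
    """

    site_id: str
    probs: np.ndarray
    dosage: float
    hard_call: int | None
    n_alt: int
    n_total: int


def hwe_prior(eaf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-f)^2, 2f(1-f), f^2)."""
    if not 0.0 < eaf < 1.0:
        raise ValueError(f"EAF must lie in (0, 1); got {eaf}")
    f = eaf
    return np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f**2])


def _prior_weights(draws: PosteriorDraws, prior_mode: str, eaf: float | None) -> np.ndarray:
    if prior_mode == "learned_theta":
        return draws.posterior_mean_theta()
    if prior_mode == "hwe":
        if eaf is None:
            raise ValueError("prior_mode='hwe' requires an effect allele frequency")
        return hwe_prior(eaf)
    raise ValueError(f"unknown prior_mode {prior_mode!r}")


def _draw_params(draws: PosteriorDraws, point_estimate: bool, max_draws: int | None):
    """(S, 3) mu and kappa arrays used for the likelihood average."""
    mu = draws.flat("mu")
    kappa = draws.flat("kappa")
    if point_estimate:
        return mu.mean(axis=0, keepdims=True), kappa.mean(axis=0, keepdims=True)
    if max_draws is not None and mu.shape[0] > max_draws:
        idx = np.linspace(0, mu.shape[0] - 1, max_draws).astype(int)
        mu, kappa = mu[idx], kappa[idx]
    return mu, kappa


def _log_marginal_lik(k, n, mu, kappa):
    """log (1/S) Σ_s BB(k | n, mu_g^s, kappa_g^s) for pair arrays.

    k, n: (P,); mu, kappa: (S, 3).  Returns (P, 3).
    """
    ll = betabin_logpmf(
        k[:, None, None], n[:, None, None], mu[None, :, :], kappa[None, :, :]
    )
    return logsumexp(ll, axis=1) - np.log(mu.shape[0])


def genotype_posterior(
    count: AlleleCount,
    draws: PosteriorDraws,
    prior_mode: str = "learned_theta",
    eaf: float | None = None,
    point_estimate: bool = False,
) -> np.ndarray:
    """Posterior genotype probabilities (3-simplex) for one site.

    A site with no reads returns the prior weights unchanged.
    """
    pi = _prior_weights(draws, prior_mode, eaf)
    mu, kappa = _draw_params(draws, point_estimate, None)
    logm = _log_marginal_lik(
        np.array([count.n_alt]), np.array([count.n_total]), mu, kappa
    )[0]
    with np.errstate(divide="ignore"):
        logp = np.log(pi) + logm
    probs = np.exp(logp - logsumexp(logp))
    return probs / probs.sum()


def hard_call(probs: np.ndarray, threshold: float = 0.99) -> int | None:
    """Most probable genotype if its probability reaches ``threshold``
    (inclusive), else ``None``.  Argmax ties break toward the smaller
    genotype index."""
    if not 1.0 / 3.0 < threshold <= 1.0:
        raise ValueError(
            f"threshold must lie in (1/3, 1]; got {threshold} "
            "(at or below 1/3 every site would always be called)"
        )
    probs = np.asarray(probs, dtype=float)
    g = int(np.argmax(probs))
    return g if probs[g] >= threshold else None


def call_sample(
    counts: list[AlleleCount],
    draws: PosteriorDraws,
    threshold: float = 0.99,
    prior_mode: str = "learned_theta",
    eaf: float | None = None,
    point_estimate: bool = False,
    max_draws: int | None = None,
) -> list[GenotypeCall]:
    """Call genotypes at every site of one individual, order-preserving.

    Sites are conditionally independent given the parameters, so the
    computation is vectorized over the unique (n_alt, n_total) pairs.
    ``max_draws`` optionally thins the posterior draws (evenly strided) used
    in the Monte-Carlo likelihood average.
    """
    if not counts:
        return []
    pi = _prior_weights(draws, prior_mode, eaf)
    mu, kappa = _draw_params(draws, point_estimate, max_draws)

    pairs = np.array([[c.n_alt, c.n_total] for c in counts])
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    logm = np.empty((uniq.shape[0], 3))
    chunk = max(1, int(2e6 // max(1, mu.shape[0])))
    for start in range(0, uniq.shape[0], chunk):
        sl = slice(start, start + chunk)
        logm[sl] = _log_marginal_lik(
            uniq[sl, 0].astype(float), uniq[sl, 1].astype(float), mu, kappa
        )
    with np.errstate(divide="ignore"):
        logp = np.log(pi)[None, :] + logm
    probs_uniq = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    probs_uniq /= probs_uniq.sum(axis=1, keepdims=True)

    calls = []
    for i, c in enumerate(counts):
        p = probs_uniq[inverse[i]]
        calls.append(
            GenotypeCall(
                site_id=c.site_id,
                probs=p,
                dosage=float(p[1] + 2.0 * p[2]),
                hard_call=hard_call(p, threshold),
                n_alt=c.n_alt,
                n_total=c.n_total,
            )
        )
    return calls
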
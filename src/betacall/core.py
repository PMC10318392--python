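"""Beta-binomial mixture model for genotype-specific RNA-seq read counts.

At a biallelic exonic SNP covered by ``n_total`` RNA-seq reads, the number of
reads carrying the alternative allele is modelled as a mixture of three
beta-binomial distributions, one per genotype g ∈ {0, 1, 2} (copies of the
alternative allele).  The beta-binomial captures the extra-binomial variance
of heterozygote counts caused by allele-specific expression, and learned
component means absorb reference mapping bias (the het mean typically sits
below 0.5).

Parameterization: each component has mean ``mu_g`` ∈ (0, 1) and concentration
``kappa_g = alpha_g + beta_g`` > 0, with ``alpha_g = mu_g * kappa_g`` and
``beta_g = (1 - mu_g) * kappa_g``.  The overdispersion on the (0, 1) scale,
``lambda_g = 1 / (1 + kappa_g)``, is exposed as a derived quantity.  Mixture
weights ``theta`` live on the 3-simplex.

Everything here is pure computation in log space; sampling, calling and I/O
live in sibling modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln, logsumexp, xlogy

__all__ = [
    "AlleleCount",
    "ComponentParams",
    "MixtureParams",
    "PriorSpec",
    "betabin_logpmf",
    "mixture_loglik",
    "log_prior",
    "reparam_from_ab",
    "reparam_to_ab",
]


@dataclass(frozen=True)
class AlleleCount:
    """Observed reads at one SNP: alt-supporting count out of total depth."""

    site_id: str
    n_alt: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_alt < 0 or self.n_total < 0:
            raise ValueError(
                f"{self.site_id}: negative read count (n_alt={self.n_alt}, "
                f"n_total={self.n_total})"
            )
        if self.n_alt > self.n_total:
            raise ValueError(
                f"{self.site_id}: n_alt={self.n_alt} exceeds n_total={self.n_total}"
            )


@dataclass(frozen=True)
class ComponentParams:
    """Per-genotype beta-binomial parameters (mean and concentration).

    ``mu`` must be strictly ascending across g = 0, 1, 2 — the identifiability
    ordering that pins component g to genotype g (hom-ref, het, hom-alt).
    """

    mu: np.ndarray
    kappa: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        kappa = np.asarray(self.kappa, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "kappa", kappa)
        if mu.shape != (3,) or kappa.shape != (3,):
            raise ValueError("mu and kappa must be length-3 vectors")
        if np.any(mu <= 0) or np.any(mu >= 1):
            raise ValueError(f"mu must lie in (0, 1); got {mu}")
        if not np.all(np.diff(mu) > 0):
            raise ValueError(f"mu must be strictly ascending; got {mu}")
        if np.any(kappa <= 0):
            raise ValueError(f"kappa must be positive; got {kappa}")

    @property
    def alpha(self) -> np.ndarray:
        return self.mu * self.kappa

    @property
    def beta(self) -> np.ndarray:
        return (1.0 - self.mu) * self.kappa

    @property
    def lambda_overdisp(self) -> np.ndarray:
        """Overdispersion on the (0, 1) scale: 1 / (1 + kappa)."""
        return 1.0 / (1.0 + self.kappa)


@dataclass(frozen=True)
class MixtureParams:
    """Mixture weights over genotypes plus the component parameters."""

    theta: np.ndarray
    components: ComponentParams

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.shape != (3,):
            raise ValueError("theta must be a length-3 vector")
        if np.any(theta < 0):
            raise ValueError(f"theta must be non-negative; got {theta}")
        if abs(theta.sum() - 1.0) > 1e-8:
            raise ValueError(f"theta must sum to 1; got sum {theta.sum()!r}")
        object.__setattr__(self, "theta", theta / theta.sum())


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the model priors.

    theta ~ Dirichlet(dirichlet_conc); mu_g ~ Beta(alpha_hyper_g, beta_hyper_g);
    kappa_g ~ Gamma(alpha_hyper_g + beta_hyper_g, rate=1).  The defaults place
    component means near 0.002 / 0.5 / 0.998 with concentrations around
    500 / 20 / 500 — informative priors elicited for genotype read-count
    distributions at well-covered exonic SNPs.
    """

    dirichlet_conc: np.ndarray = field(default_factory=lambda: np.ones(3))
    alpha_hyper: np.ndarray = field(default_factory=lambda: np.array([1.0, 10.0, 499.0]))
    beta_hyper: np.ndarray = field(default_factory=lambda: np.array([499.0, 10.0, 1.0]))

    def __post_init__(self) -> None:
        for name in ("dirichlet_conc", "alpha_hyper", "beta_hyper"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a length-3 vector")
            if np.any(v <= 0):
                raise ValueError(f"{name} entries must be positive; got {v}")

    @property
    def gamma_shape(self) -> np.ndarray:
        """Shape of the Gamma prior on each concentration: alpha_g + beta_g."""
        return self.alpha_hyper + self.beta_hyper


def _check_mu_kappa(mu, kappa) -> None:
    mu = np.asarray(mu, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError(f"mu must lie in the open interval (0, 1); got {mu}")
    if np.any(kappa <= 0):
        raise ValueError(f"kappa must be positive; got {kappa}")


def betabin_logpmf(n_alt, n_total, mu, kappa):
    """Log pmf of the beta-binomial, BB(n_alt | n_total, mu, kappa).

    With alpha = mu*kappa and beta = (1-mu)*kappa,

        P(k | n) = C(n, k) * B(k + alpha, n - k + beta) / B(alpha, beta).

    Computed with log-gamma functions so depths of 1e6 reads do not overflow.
    Broadcasts over array arguments; an empty observation (n_total = 0)
    has log pmf 0.

    Parameters
    ----------
    n_alt, n_total
        Reads supporting the alternative allele, and total reads, at a site.
    mu, kappa
        Component mean in (0, 1) and concentration > 0.
    """
    k = np.asarray(n_alt)
    n = np.asarray(n_total)
    if np.any(k < 0) or np.any(n < 0):
        raise ValueError("read counts must be non-negative")
    if np.any(k > n):
        raise ValueError("n_alt must not exceed n_total")
    _check_mu_kappa(mu, kappa)
    k = k.astype(float)
    n = n.astype(float)
    mu = np.asarray(mu, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    a = mu * kappa
    b = (1.0 - mu) * kappa
    out = (
        gammaln(n + 1.0)
        - gammaln(k + 1.0)
        - gammaln(n - k + 1.0)
        + betaln(k + a, n - k + b)
        - betaln(a, b)
    )
    if out.ndim == 0:
        return float(out)
    return out


def mixture_loglik(counts, params: MixtureParams) -> float:
    """Marginal log-likelihood of allele counts under the 3-component mixture.

    Sums, over sites l, log Σ_g theta_g BB(n_alt_l | n_total_l, mu_g, kappa_g)
    with the genotype label marginalized analytically (log-sum-exp).
    """
    if len(counts) == 0:
        raise ValueError("mixture_loglik requires a non-empty list of counts")
    k = np.array([c.n_alt for c in counts], dtype=float)
    n = np.array([c.n_total for c in counts], dtype=float)
    comp = params.components
    ll = betabin_logpmf(k[:, None], n[:, None], comp.mu[None, :], comp.kappa[None, :])
    with np.errstate(divide="ignore"):
        log_theta = np.log(params.theta)
    return float(np.sum(logsumexp(ll + log_theta[None, :], axis=1)))


def log_prior(params: MixtureParams, priors: PriorSpec) -> float:
    """Log prior density of the mixture parameters.

    Dirichlet on theta, Beta(alpha_hyper_g, beta_hyper_g) on each mu_g and
    Gamma(alpha_hyper_g + beta_hyper_g, rate 1) on each kappa_g.  Points on
    the boundary of support return -inf rather than raising.
    """
    theta = params.theta
    mu = params.components.mu
    kappa = params.components.kappa
    if np.any(theta <= 0) or np.any(mu <= 0) or np.any(mu >= 1) or np.any(kappa <= 0):
        return -math.inf
    c = priors.dirichlet_conc
    lp = gammaln(c.sum()) - gammaln(c).sum() + np.sum(xlogy(c - 1.0, theta))
    a, b = priors.alpha_hyper, priors.beta_hyper
    lp += np.sum((a - 1.0) * np.log(mu) + (b - 1.0) * np.log1p(-mu) - betaln(a, b))
    shape = priors.gamma_shape
    lp += np.sum((shape - 1.0) * np.log(kappa) - kappa - gammaln(shape))
    return float(lp)


def reparam_from_ab(alpha: float, beta: float) -> tuple[float, float]:
    """Map beta parameters (alpha, beta) to (mu, lambda).

    mu = alpha / (alpha + beta); lambda = 1 / (1 + alpha + beta).
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError(f"alpha and beta must be positive; got ({alpha}, {beta})")
    s = alpha + beta
    return alpha / s, 1.0 / (1.0 + s)


def reparam_to_ab(mu: float, lambda_overdisp: float) -> tuple[float, float]:
    """Inverse of :func:`reparam_from_ab`: (mu, lambda) back to (alpha, beta)."""
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mu must lie in (0, 1); got {mu}")
    if not 0.0 < lambda_overdisp < 1.0:
        raise ValueError(f"lambda must lie in (0, 1); got {lambda_overdisp}")
    kappa = 1.0 / lambda_overdisp - 1.0
    return mu * kappa, (1.0 - mu) * kappa
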
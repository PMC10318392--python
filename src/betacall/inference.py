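"""Posterior inference for the beta-binomial mixture: training-set selection,
MCMC sampling, convergence diagnostics and fitted-model serialization.

The model is fitted in two steps, mirroring how the genotyper is meant to be
used: learn the mixture parameters once from a random subset of well-covered
SNPs (default 1000 sites with at least 10 reads), then reuse the posterior
draws to call genotypes across all sites — including sites from other samples
of the same study, since the learned read-count distributions transfer.

The sampler is a self-contained adaptive Metropolis-within-Gibbs on
transformed coordinates (stick-breaking theta, logit mu, log kappa) targeting
the posterior with the genotype labels marginalized analytically.  Label
switching is resolved by truncating the prior to strictly ascending component
means, which the strongly separated default priors make essentially
non-binding.  Proposal scales adapt during warmup only, so the kept draws are
a valid Markov chain.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln
from scipy.special import expit, logit

from .core import AlleleCount, PriorSpec

__all__ = [
    "TrainingSet",
    "PosteriorDraws",
    "FitSummary",
    "select_training_snps",
    "fit_mixture",
    "diagnose",
    "save_fit",
    "load_fit",
]

PARAM_NAMES = [f"{p}[{g}]" for p in ("theta", "mu", "kappa") for g in range(3)]


@dataclass(frozen=True)
class TrainingSet:
    """A depth-filtered random subset of sites used to learn the mixture."""

    counts: list[AlleleCount]
    min_depth: int
    requested_size: int
    seed: int
    n_eligible: int

    @property
    def shortfall(self) -> int:
        """How many sites short of the requested size the selection fell."""
        return max(0, self.requested_size - len(self.counts))


def select_training_snps(
    counts: list[AlleleCount],
    requested_size: int = 1000,
    min_depth: int = 10,
    seed: int = 0,
) -> TrainingSet:
    """Uniform random sample (without replacement) of sites with
    ``n_total >= min_depth``.

    If fewer sites pass the depth filter than requested, all eligible sites
    are returned and the shortfall is recorded on the result.
    """
    if len(counts) == 0:
        raise ValueError("no input sites to select from")
    eligible = [c for c in counts if c.n_total >= min_depth]
    if not eligible:
        raise ValueError(
            f"no sites pass the depth filter n_total >= {min_depth} "
            f"(of {len(counts)} input sites)"
        )
    rng = np.random.default_rng(seed)
    if len(eligible) <= requested_size:
        chosen = list(eligible)
    else:
        idx = rng.choice(len(eligible), size=requested_size, replace=False)
        chosen = [eligible[i] for i in sorted(idx)]
    return TrainingSet(
        counts=chosen,
        min_depth=min_depth,
        requested_size=requested_size,
        seed=seed,
        n_eligible=len(eligible),
    )


@dataclass
class PosteriorDraws:
    """Kept MCMC draws with chain bookkeeping.

    Arrays are indexed (chain, kept-iteration, component).  Every theta draw
    is a 3-simplex and every mu draw is strictly ascending across components.
    """

    theta: np.ndarray
    mu: np.ndarray
    kappa: np.ndarray
    n_warmup: int
    seed: int

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_kept_total(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws of one parameter block pooled over chains, shape (S, 3)."""
        return getattr(self, name).reshape(-1, 3)

    def posterior_mean_theta(self) -> np.ndarray:
        return self.flat("theta").mean(axis=0)


@dataclass
class FitSummary:
    """Posterior summaries plus split-chain convergence diagnostics."""

    table: "object"  # pandas.DataFrame indexed by parameter name
    converged: bool
    rhat_threshold: float = 1.05

    def __getitem__(self, param: str):
        return self.table.loc[param]


# ---------------------------------------------------------------------------
# Sampler internals
# ---------------------------------------------------------------------------


class _Target:
    """Log-posterior on unconstrained coordinates, with cached per-component
    likelihood columns so block updates only recompute what changed.

    Coordinates: u (2,) stick-breaking logits for theta; m (3,) logit mu;
    h (3,) log kappa.  Counts are aggregated over unique (n_alt, n_total)
    pairs with multiplicity weights.
    """

    def __init__(self, counts: list[AlleleCount], priors: PriorSpec):
        if counts:
            pairs = np.array([[c.n_alt, c.n_total] for c in counts], dtype=float)
            uniq, w = np.unique(pairs, axis=0, return_counts=True)
            self.k = uniq[:, 0]
            self.n = uniq[:, 1]
            self.w = w.astype(float)
            self.lchoose = (
                gammaln(self.n + 1.0)
                - gammaln(self.k + 1.0)
                - gammaln(self.n - self.k + 1.0)
            )
        else:  # prior-only target (used for prior predictive checks)
            self.k = self.n = self.w = self.lchoose = np.zeros(0)
        self.priors = priors
        # Beta and Gamma prior normalizers, precomputed once.
        a, b = priors.alpha_hyper, priors.beta_hyper
        self._beta_norm = -betaln(a, b)
        self._gamma_shape = priors.gamma_shape
        self._gamma_norm = -gammaln(self._gamma_shape)

    def component_col(self, mu_g: float, kappa_g: float) -> np.ndarray:
        a = mu_g * kappa_g
        b = (1.0 - mu_g) * kappa_g
        return self.lchoose + betaln(self.k + a, self.n - self.k + b) - betaln(a, b)

    def loglik(self, log_theta: np.ndarray, ll: np.ndarray) -> float:
        if self.k.size == 0:
            return 0.0
        z = ll + log_theta[None, :]
        m = z.max(axis=1)
        return float(np.dot(self.w, m + np.log(np.exp(z - m[:, None]).sum(axis=1))))

    @staticmethod
    def theta_from_u(u: np.ndarray) -> np.ndarray:
        v1, v2 = expit(u[0]), expit(u[1])
        return np.array([v1, (1.0 - v1) * v2, (1.0 - v1) * (1.0 - v2)])

    def logprior_theta(self, u: np.ndarray) -> tuple[float, np.ndarray]:
        """Dirichlet log density plus the stick-breaking log-Jacobian."""
        theta = self.theta_from_u(u)
        if np.any(theta <= 0.0):
            return -math.inf, theta
        c = self.priors.dirichlet_conc
        lp = gammaln(c.sum()) - gammaln(c).sum() + np.sum((c - 1.0) * np.log(theta))
        v1, v2 = expit(u[0]), expit(u[1])
        # |J| = v1(1-v1) * (1-v1) * v2(1-v2)
        lp += math.log(v1) + 2.0 * math.log1p(-v1) + math.log(v2) + math.log1p(-v2)
        return lp, theta

    def logprior_comp(self, g: int, m_g: float, h_g: float) -> float:
        """Beta x Gamma log prior for component g plus logit/log Jacobians."""
        mu = expit(m_g)
        kappa = math.exp(h_g)
        if not (0.0 < mu < 1.0) or not np.isfinite(kappa) or kappa <= 0.0:
            return -math.inf
        a = self.priors.alpha_hyper[g]
        b = self.priors.beta_hyper[g]
        lp = (a - 1.0) * math.log(mu) + (b - 1.0) * math.log1p(-mu) + self._beta_norm[g]
        lp += (
            (self._gamma_shape[g] - 1.0) * h_g
            - kappa
            + self._gamma_norm[g]
        )
        # Jacobians: d mu/d m = mu(1-mu); d kappa/d h = kappa
        lp += math.log(mu) + math.log1p(-mu) + h_g
        return lp


def _run_chain(
    target: _Target,
    rng: np.random.Generator,
    n_warmup: int,
    n_keep: int,
    init_jitter: float = 0.3,
):
    priors = target.priors
    # Initialize near the prior means, jittered per chain for overdispersion.
    mu0 = priors.alpha_hyper / (priors.alpha_hyper + priors.beta_hyper)
    m = logit(mu0) + init_jitter * rng.standard_normal(3)
    h = np.log(priors.gamma_shape) + init_jitter * rng.standard_normal(3)
    u = init_jitter * rng.standard_normal(2)

    mu = expit(m)
    if not np.all(np.diff(mu) > 0):  # jitter broke the ordering; restart from means
        m = logit(mu0)
        mu = expit(m)
    kappa = np.exp(h)

    ll = np.column_stack([target.component_col(mu[g], kappa[g]) for g in range(3)])
    lp_theta, theta = target.logprior_theta(u)
    with np.errstate(divide="ignore"):
        log_theta = np.log(theta)
    cur_lik = target.loglik(log_theta, ll)
    lp_comp = np.array([target.logprior_comp(g, m[g], h[g]) for g in range(3)])

    scales = {"theta": 0.3}
    for g in range(3):
        scales[("m", g)] = 0.3
        scales[("h", g)] = 0.3
    target_accept = 0.38  # scalar random-walk optimum is ~0.44; slightly conservative

    keep_theta = np.empty((n_keep, 3))
    keep_mu = np.empty((n_keep, 3))
    keep_kappa = np.empty((n_keep, 3))

    total = n_warmup + n_keep
    for it in range(total):
        adapt = it < n_warmup
        gamma_t = (it + 1) ** -0.6

        # --- theta block ---
        u_prop = u + scales["theta"] * rng.standard_normal(2)
        lp_prop, theta_prop = target.logprior_theta(u_prop)
        accepted = False
        if np.isfinite(lp_prop):
            with np.errstate(divide="ignore"):
                log_theta_prop = np.log(theta_prop)
            lik_prop = target.loglik(log_theta_prop, ll)
            if math.log(rng.uniform()) < (lik_prop + lp_prop) - (cur_lik + lp_theta):
                u, theta, log_theta = u_prop, theta_prop, log_theta_prop
                lp_theta, cur_lik = lp_prop, lik_prop
                accepted = True
        if adapt:
            scales["theta"] = float(
                np.exp(np.log(scales["theta"]) + gamma_t * (accepted - target_accept))
            )

        # --- component coordinates: scalar updates of logit-mu then log-kappa ---
        for g in range(3):
            for coord in ("m", "h"):
                if coord == "m":
                    m_p = m[g] + scales[("m", g)] * rng.standard_normal()
                    h_p = h[g]
                else:
                    m_p = m[g]
                    h_p = h[g] + scales[("h", g)] * rng.standard_normal()
                mu_p = expit(m_p)
                # ascending-mu truncation (identifiability)
                lo = mu[g - 1] if g > 0 else 0.0
                hi = mu[g + 1] if g < 2 else 1.0
                accepted = False
                if lo < mu_p < hi:
                    lp_p = target.logprior_comp(g, m_p, h_p)
                    if np.isfinite(lp_p):
                        col_p = target.component_col(mu_p, math.exp(h_p))
                        ll_p = ll.copy()
                        ll_p[:, g] = col_p
                        lik_p = target.loglik(log_theta, ll_p)
                        if math.isnan(lik_p):
                            raise RuntimeError(
                                f"non-finite log-likelihood at mu[{g}]={mu_p}, "
                                f"kappa[{g}]={math.exp(h_p)}"
                            )
                        if math.log(rng.uniform()) < (lik_p + lp_p) - (
                            cur_lik + lp_comp[g]
                        ):
                            m[g], h[g] = m_p, h_p
                            mu[g], kappa[g] = mu_p, math.exp(h_p)
                            ll = ll_p
                            lp_comp[g], cur_lik = lp_p, lik_p
                            accepted = True
                if adapt:
                    scales[(coord, g)] = float(
                        np.exp(
                            np.log(scales[(coord, g)])
                            + gamma_t * (accepted - target_accept)
                        )
                    )

        if it >= n_warmup:
            j = it - n_warmup
            keep_theta[j] = theta
            keep_mu[j] = mu
            keep_kappa[j] = kappa

    return keep_theta, keep_mu, keep_kappa


def fit_mixture(
    training: TrainingSet,
    priors: PriorSpec | None = None,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_keep_per_chain: int = 1000,
    seed: int = 0,
    _allow_empty: bool = False,
) -> PosteriorDraws:
    """Sample the posterior of the mixture parameters by MCMC.

    Defaults follow the standard budget of four chains with 1000 kept draws
    each after 1000 warmup iterations (4000 posterior draws total).  The run
    is bitwise reproducible given ``seed``; chains use independent streams
    spawned from it.

    Set ``_allow_empty`` to sample the prior with no data (testing hook).
    """
    if priors is None:
        priors = PriorSpec()
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if n_chains < 2:
        warnings.warn("fewer than 2 chains: split-Rhat diagnostics unavailable")
    if n_warmup < 0 or n_keep_per_chain < 1:
        raise ValueError("need n_warmup >= 0 and n_keep_per_chain >= 1")
    if len(training.counts) == 0 and not _allow_empty:
        raise ValueError("empty training set")

    target = _Target(training.counts, priors)
    streams = np.random.SeedSequence(seed).spawn(n_chains)
    theta = np.empty((n_chains, n_keep_per_chain, 3))
    mu = np.empty((n_chains, n_keep_per_chain, 3))
    kappa = np.empty((n_chains, n_keep_per_chain, 3))
    for c in range(n_chains):
        rng = np.random.default_rng(streams[c])
        theta[c], mu[c], kappa[c] = _run_chain(target, rng, n_warmup, n_keep_per_chain)
    return PosteriorDraws(theta=theta, mu=mu, kappa=kappa, n_warmup=n_warmup, seed=seed)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def diagnose(draws: PosteriorDraws, rhat_threshold: float = 1.05) -> FitSummary:
    """Split-chain R-hat, effective sample size and posterior summaries.

    The convergence flag is ``all(rhat < rhat_threshold)``.  Requires at
    least two chains and ten kept draws per chain.
    """
    import pandas as pd

    if draws.n_chains < 2:
        raise ValueError("split-Rhat requires at least 2 chains")
    if draws.theta.shape[1] < 10:
        raise ValueError("need at least 10 kept draws per chain")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        idata = az.from_dict(
            posterior={
                "theta": draws.theta,
                "mu": draws.mu,
                "kappa": draws.kappa,
            }
        )
        rhat_ds = az.rhat(idata, method="split")
        ess_ds = az.ess(idata, method="mean")

    rows = []
    for p in ("theta", "mu", "kappa"):
        arr = getattr(draws, p).reshape(-1, 3)
        rh = np.asarray(rhat_ds[p])
        es = np.asarray(ess_ds[p])
        for g in range(3):
            x = arr[:, g]
            r = float(rh[g])
            rows.append(
                {
                    "parameter": f"{p}[{g}]",
                    "mean": float(x.mean()),
                    "ci_2.5": float(np.percentile(x, 2.5)),
                    "ci_97.5": float(np.percentile(x, 97.5)),
                    "rhat": r if np.isfinite(r) else math.inf,
                    "ess": float(es[g]),
                }
            )
    table = pd.DataFrame(rows).set_index("parameter")
    converged = bool(np.all(table["rhat"] < rhat_threshold))
    return FitSummary(table=table, converged=converged, rhat_threshold=rhat_threshold)


# ---------------------------------------------------------------------------
# Fitted-model serialization (fit once, call many)
# ---------------------------------------------------------------------------


def save_fit(
    path,
    draws: PosteriorDraws,
    priors: PriorSpec,
    summary: FitSummary | None = None,
    extra: dict | None = None,
) -> None:
    """Write a fitted model to a plain-text JSON file, round-trippable with
    :func:`load_fit`.  Floats are serialized at full precision, so identical
    fits produce byte-identical files."""
    obj = {
        "format": "betacall-fit-v1",
        "seed": draws.seed,
        "n_warmup": draws.n_warmup,
        "n_chains": draws.n_chains,
        "priors": {
            "dirichlet_conc": priors.dirichlet_conc.tolist(),
            "alpha_hyper": priors.alpha_hyper.tolist(),
            "beta_hyper": priors.beta_hyper.tolist(),
        },
        "draws": {
            "theta": draws.theta.tolist(),
            "mu": draws.mu.tolist(),
            "kappa": draws.kappa.tolist(),
        },
    }
    if summary is not None:
        obj["summary"] = {
            "converged": summary.converged,
            "rhat_threshold": summary.rhat_threshold,
            "table": summary.table.reset_index().to_dict(orient="records"),
        }
    if extra:
        obj["config"] = extra
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_fit(path) -> tuple[PosteriorDraws, PriorSpec]:
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("format") != "betacall-fit-v1":
        raise ValueError(f"{path}: not a betacall fitted-model file")
    priors = PriorSpec(
        dirichlet_conc=np.array(obj["priors"]["dirichlet_conc"]),
        alpha_hyper=np.array(obj["priors"]["alpha_hyper"]),
        beta_hyper=np.array(obj["priors"]["beta_hyper"]),
    )
    draws = PosteriorDraws(
        theta=np.array(obj["draws"]["theta"]),
        mu=np.array(obj["draws"]["mu"]),
        kappa=np.array(obj["draws"]["kappa"]),
        n_warmup=obj["n_warmup"],
        seed=obj["seed"],
    )
    return draws, priors
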
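"""Posterior sampling for the variance-decomposition models.

Two parameterizations are used, both sampled in an unconstrained space by
adaptive scalar Metropolis-within-Gibbs with diminishing adaptation:

* constrained (canonical model): additive-log-ratio coordinates of the
  simplex [U, T, B, N] (technical noise as reference) plus log lengthscale;
  priors are Dirichlet(1, 1, 1, 1) on the simplex and gamma(shape 3.1,
  mean 10 months) on the lengthscale.
* unconstrained (model-selection stage): log variance magnitude per included
  component with half-normal(sd 1) priors, plus log lengthscale per
  time-varying component with the same gamma prior.

Chains start from prior draws.  The stored log un-normalized posterior is
the exact target density in the transformed space (including Jacobians), as
required by the evidence estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from microdyn.gp.design import SamplingDesign
from microdyn.gp.kernels import (
    GPLikelihood,
    GPParams,
    ModelSpec,
    BIOLOGICAL_NOISE,
    INTER_INDIVIDUAL,
    OU,
    TECHNICAL,
)

__all__ = ["PriorSpec", "PosteriorResult", "run_mcmc", "rhat", "log_unnormalized_posterior"]


@dataclass(frozen=True)
class PriorSpec:
    """Priors for both fitting stages.

    The lengthscale prior gamma(shape 3.1, mean 10 months) keeps the
    timescale away from both the replicate limit (too short) and the study
    span (too long), which is what makes the time-varying component
    identifiable next to biological noise and inter-individual differences.
    """

    lengthscale_shape: float = 3.1
    lengthscale_mean: float = 10.0  #: months
    dirichlet_alpha: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    magnitude_sd: float = 1.0  #: half-normal sd for selection-stage magnitudes

    @property
    def lengthscale_scale(self) -> float:
        return self.lengthscale_mean / self.lengthscale_shape

    def log_lengthscale_prior(self, log_l: float) -> float:
        # gamma prior on l plus the log-parameterization Jacobian
        l = np.exp(log_l)
        return float(
            stats.gamma.logpdf(l, a=self.lengthscale_shape, scale=self.lengthscale_scale)
            + log_l
        )

    def log_magnitude_prior(self, log_m: float) -> float:
        # half-normal on m > 0 plus Jacobian of m = exp(log_m)
        m = np.exp(log_m)
        return float(
            0.5 * np.log(2.0 / np.pi)
            - np.log(self.magnitude_sd)
            - m**2 / (2.0 * self.magnitude_sd**2)
            + log_m
        )


def _softmax4(z: np.ndarray) -> np.ndarray:
    """[U, T, B, N] from three free logits (N is the reference class)."""
    logits = np.concatenate([z, [0.0]])
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


class _ConstrainedTarget:
    """Target density over (alr(U, T, B, N), log l) for the canonical model."""

    param_names = ("U", "T", "B", "N", "lengthscale")
    dim = 4

    def __init__(self, likelihood: GPLikelihood, y: np.ndarray, priors: PriorSpec):
        self.likelihood = likelihood
        self.y = y
        self.priors = priors
        alpha = np.asarray(priors.dirichlet_alpha, dtype=float)
        self._log_dirichlet_const = float(
            special.gammaln(alpha.sum()) - special.gammaln(alpha).sum()
        )
        self._alpha = alpha
        self.spec = ModelSpec.canonical()

    def log_posterior(self, theta: np.ndarray) -> float:
        x = _softmax4(theta[:3])
        if (x <= 0).any():
            return -np.inf
        log_l = theta[3]
        if not np.isfinite(log_l) or abs(log_l) > 30:
            return -np.inf
        # Dirichlet prior + ALR Jacobian (prod of simplex coordinates)
        logp = self._log_dirichlet_const + float(((self._alpha - 1) * np.log(x)).sum())
        logp += float(np.log(x).sum())
        logp += self.priors.log_lengthscale_prior(log_l)
        if not np.isfinite(logp):
            return -np.inf
        u, t, b, n = x
        ll = self.likelihood.loglik(
            self.y,
            {TECHNICAL: n, BIOLOGICAL_NOISE: b, INTER_INDIVIDUAL: u, OU: t},
            {OU: float(np.exp(log_l))},
        )
        return logp + ll

    def natural(self, theta: np.ndarray) -> dict[str, float]:
        u, t, b, n = _softmax4(theta[:3])
        return {
            "U": float(u),
            "T": float(t),
            "B": float(b),
            "N": float(n),
            "lengthscale": float(np.exp(theta[3])),
        }

    def sample_prior(self, rng: np.random.Generator) -> np.ndarray:
        x = rng.dirichlet(self._alpha)
        x = np.clip(x, 1e-12, None)
        z = np.log(x[:3] / x[3])
        log_l = np.log(
            rng.gamma(self.priors.lengthscale_shape, self.priors.lengthscale_scale)
        )
        return np.concatenate([z, [log_l]])


class _UnconstrainedTarget:
    """Target density over (log magnitudes, log lengthscales) for any model."""

    def __init__(
        self, likelihood: GPLikelihood, y: np.ndarray, spec: ModelSpec, priors: PriorSpec
    ):
        self.likelihood = likelihood
        self.y = y
        self.spec = spec
        self.priors = priors
        self._mag_names = spec.ordered_components
        self._ls_names = spec.lengthscale_components
        self.param_names = tuple(self._mag_names) + tuple(
            f"{c}_lengthscale" for c in self._ls_names
        )
        self.dim = len(self.param_names)

    def log_posterior(self, theta: np.ndarray) -> float:
        if np.abs(theta).max() > 30:
            return -np.inf
        k = len(self._mag_names)
        logp = 0.0
        for v in theta[:k]:
            logp += self.priors.log_magnitude_prior(float(v))
        for v in theta[k:]:
            logp += self.priors.log_lengthscale_prior(float(v))
        magnitudes = {c: float(np.exp(v)) for c, v in zip(self._mag_names, theta[:k])}
        lengthscales = {c: float(np.exp(v)) for c, v in zip(self._ls_names, theta[k:])}
        return logp + self.likelihood.loglik(self.y, magnitudes, lengthscales)

    def natural(self, theta: np.ndarray) -> dict[str, float]:
        return {name: float(np.exp(v)) for name, v in zip(self.param_names, theta)}

    def sample_prior(self, rng: np.random.Generator) -> np.ndarray:
        k = len(self._mag_names)
        mags = np.log(np.abs(rng.normal(0.0, self.priors.magnitude_sd, size=k)) + 1e-12)
        ls = np.log(
            rng.gamma(
                self.priors.lengthscale_shape,
                self.priors.lengthscale_scale,
                size=len(self._ls_names),
            )
        )
        return np.concatenate([mags, ls])


def log_unnormalized_posterior(
    y: np.ndarray,
    params,
    spec: ModelSpec,
    priors: PriorSpec,
    design: SamplingDesign,
) -> float:
    """Log un-normalized posterior of natural-space parameters.

    ``params`` is a :class:`GPParams` for the canonical constrained model
    (off-simplex parameters give ``-inf``) or ``(magnitudes, lengthscales)``
    mappings for an unconstrained model.  The density is the Gaussian
    log-likelihood of ``y`` under N(0, K) plus the log priors on the natural
    parameters (no transform Jacobians).
    """
    likelihood = GPLikelihood(design)
    if isinstance(params, GPParams):
        if not spec.is_canonical:
            raise ValueError("GPParams imply the canonical component set")
        if not params.on_simplex:
            return -np.inf
        x = np.array([params.u, params.t, params.b, params.n])
        if (x <= 0).any():
            return -np.inf
        alpha = np.asarray(priors.dirichlet_alpha)
        logp = float(
            special.gammaln(alpha.sum())
            - special.gammaln(alpha).sum()
            + ((alpha - 1) * np.log(x)).sum()
        )
        logp += float(
            stats.gamma.logpdf(
                params.lengthscale, a=priors.lengthscale_shape, scale=priors.lengthscale_scale
            )
        )
        return logp + likelihood.loglik(y, params.magnitudes(), params.lengthscales())
    magnitudes, lengthscales = params
    logp = 0.0
    for c in spec.ordered_components:
        m = magnitudes[c]
        logp += float(stats.halfnorm.logpdf(m, scale=priors.magnitude_sd))
    for c in spec.lengthscale_components:
        logp += float(
            stats.gamma.logpdf(
                lengthscales[c], a=priors.lengthscale_shape, scale=priors.lengthscale_scale
            )
        )
    return logp + likelihood.loglik(y, dict(magnitudes), dict(lengthscales))


@dataclass
class PosteriorResult:
    """MCMC output: per-chain draws, target log density, and diagnostics."""

    spec: ModelSpec
    param_names: tuple[str, ...]
    theta: np.ndarray = field(repr=False)  #: (chains, draws, dim) transformed space
    log_post: np.ndarray = field(repr=False)  #: (chains, draws)
    natural: dict[str, np.ndarray] = field(repr=False)  #: name -> (chains, draws)
    acceptance: np.ndarray = field(repr=False)  #: per chain
    constrained: bool = False
    seed: int | None = None
    y_fingerprint: float = 0.0

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def flat_theta(self) -> np.ndarray:
        return self.theta.reshape(-1, self.theta.shape[-1])

    def flat_log_post(self) -> np.ndarray:
        return self.log_post.reshape(-1)

    def posterior_mean(self, name: str) -> float:
        return float(self.natural[name].mean())

    def chain_means(self, name: str) -> np.ndarray:
        return self.natural[name].mean(axis=1)

    def rhat(self) -> dict[str, float]:
        out = {}
        for name, draws in self.natural.items():
            if np.ptp(draws) == 0:
                continue  # constant parameter: R-hat undefined, mixing trivially fine
            out[name] = rhat(draws)
        return out

    def max_rhat(self) -> float:
        values = self.rhat()
        return max(values.values()) if values else 1.0

    def summary(self) -> dict:
        return {
            "model": str(self.spec),
            "chains": self.n_chains,
            "draws_per_chain": self.n_draws,
            "posterior_mean": {k: self.posterior_mean(k) for k in self.natural},
            "rhat": self.rhat(),
            "acceptance": [float(a) for a in self.acceptance],
            "seed": self.seed,
        }


def rhat(chain_draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (Gelman-Rubin R-hat).

    ``chain_draws`` has shape (chains, draws); each chain is split in half,
    and R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance of the split-chain means.
    Requires >= 2 chains and >= 10 draws per chain; zero within-chain
    variance is an error.
    """
    draws = np.asarray(chain_draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 10:
        raise ValueError("R-hat needs >= 2 chains with >= 10 draws each")
    half = draws.shape[1] // 2
    split = np.concatenate([draws[:, :half], draws[:, half: 2 * half]], axis=0)
    n = split.shape[1]
    within = split.var(axis=1, ddof=1).mean()
    if within == 0:
        raise ValueError("R-hat undefined: zero within-chain variance")
    between = n * split.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))


def _make_target(likelihood, y, spec, priors, constrained):
    if constrained:
        if not spec.is_canonical:
            raise ValueError("the simplex constraint applies to the canonical model only")
        return _ConstrainedTarget(likelihood, y, priors)
    return _UnconstrainedTarget(likelihood, y, spec, priors)


def run_mcmc(
    y: np.ndarray,
    spec: ModelSpec,
    priors: PriorSpec = PriorSpec(),
    design: SamplingDesign | None = None,
    chains: int = 10,
    samples: int = 200,
    burnin: int = 30,
    thin: int = 2,
    seed: int | None = None,
    constrained: bool | None = None,
    initial_step: float = 0.5,
    prior_only: bool = False,
) -> PosteriorResult:
    """Sample the posterior of a variance-decomposition model.

    All free parameters are updated jointly (one scalar Metropolis sweep per
    iteration, every coordinate refreshed each sweep); proposal scales adapt
    per coordinate toward 44% acceptance with a diminishing schedule, so the
    chain remains valid without a hard adaptation cutoff.  Each chain starts
    from an independent prior draw; results are reproducible given ``seed``.
    """
    y = np.asarray(y, dtype=float)
    if design is None:
        raise ValueError("a SamplingDesign is required")
    if y.shape != (design.n,):
        raise ValueError(f"y has shape {y.shape}, design has {design.n} samples")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    if chains < 2:
        raise ValueError("at least 2 chains are required for convergence checks")
    if constrained is None:
        constrained = spec.is_canonical
    likelihood = GPLikelihood(design)
    if prior_only:
        class _NullLikelihood:
            @staticmethod
            def loglik(_y, _m, _l=None):
                return 0.0

        likelihood = _NullLikelihood()  # sampling the prior, for calibration checks
    target = _make_target(likelihood, y, spec, priors, constrained)
    dim = target.dim
    seed_seqs = np.random.SeedSequence(seed).spawn(chains)
    total_iters = burnin + samples * thin
    theta_out = np.empty((chains, samples, dim))
    logp_out = np.empty((chains, samples))
    acc_out = np.empty(chains)
    for c, ss in enumerate(seed_seqs):
        rng = np.random.default_rng(ss)
        theta = None
        for _ in range(100):
            cand = target.sample_prior(rng)
            lp = target.log_posterior(cand)
            if np.isfinite(lp):
                theta, logp = cand, lp
                break
        if theta is None:
            raise RuntimeError("could not find a finite-posterior prior draw")
        step = np.full(dim, initial_step)
        accepted = proposed = 0
        kept = 0
        for it in range(total_iters):
            gamma = min(0.25, 1.0 / np.sqrt(it + 1.0))
            for d in range(dim):
                prop = theta.copy()
                prop[d] += step[d] * rng.standard_normal()
                lp_prop = target.log_posterior(prop)
                proposed += 1
                accept = np.log(rng.random()) < lp_prop - logp
                if accept:
                    theta, logp = prop, lp_prop
                    accepted += 1
                step[d] *= np.exp(gamma * ((1.0 if accept else 0.0) - 0.44))
            if it >= burnin and (it - burnin) % thin == thin - 1 and kept < samples:
                theta_out[c, kept] = theta
                logp_out[c, kept] = logp
                kept += 1
        if kept != samples:
            raise RuntimeError(f"chain {c} retained {kept}/{samples} draws")
        if accepted == 0:
            raise RuntimeError(
                f"chain {c}: all {proposed} proposals rejected "
                f"(last logp {logp:.3g}); check data scaling"
            )
        acc_out[c] = accepted / proposed
    natural = {name: np.empty((chains, samples)) for name in target.param_names}
    for c in range(chains):
        for k in range(samples):
            vals = target.natural(theta_out[c, k])
            for name, v in vals.items():
                natural[name][c, k] = v
    return PosteriorResult(
        spec=spec,
        param_names=tuple(target.param_names),
        theta=theta_out,
        log_post=logp_out,
        natural=natural,
        acceptance=acc_out,
        constrained=constrained,
        seed=seed,
        y_fingerprint=float(np.sum(y * y)),
    )
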
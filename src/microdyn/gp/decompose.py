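"""Posterior summaries of the variance decomposition for ternary plotting.

Technical noise is a nuisance here, so the three biological components are
renormalized per draw, (U, T, B) / (U + T + B), and summarized by their
posterior mean: a point on the 2-simplex (the ternary diagram).  Uncertainty
is quantified by the standard error of the mean across chains; fits whose
maximal coordinate s.e.m. exceeds 0.2 are flagged low-confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from microdyn.gp.mcmc import PosteriorResult

__all__ = ["VarianceDecomposition", "decompose_variance"]

COORDINATE_NAMES = ("inter_individual", "time_varying", "biological_noise")
LOW_CONFIDENCE_SEM = 0.2


@dataclass(frozen=True)
class VarianceDecomposition:
    """Ternary coordinates (U, T, B renormalized to sum 1) with uncertainty."""

    coordinates: tuple[float, float, float]  #: order: U, T, B
    sem: tuple[float, float, float]
    technical_noise: float  #: posterior mean N
    low_confidence: bool
    lengthscale: float  #: posterior mean OU lengthscale, months

    @property
    def sem_max(self) -> float:
        return max(self.sem)

    def as_dict(self) -> dict:
        return {
            "coordinates": dict(zip(COORDINATE_NAMES, self.coordinates)),
            "sem": dict(zip(COORDINATE_NAMES, self.sem)),
            "sem_max": self.sem_max,
            "technical_noise": self.technical_noise,
            "low_confidence": self.low_confidence,
            "lengthscale_months": self.lengthscale,
        }


def decompose_variance(posterior: PosteriorResult) -> VarianceDecomposition:
    """Summarize a constrained fit as ternary coordinates.

    Per draw, the technical component is normalized out: coordinates are
    (U, T, B) / (U + T + B).  The s.e.m. of each coordinate is the standard
    deviation of per-chain means divided by sqrt(n_chains); the
    low-confidence flag fires when the maximal coordinate s.e.m. exceeds
    0.2.  Draws with U + T + B = 0 are excluded with a warning.
    """
    if not posterior.constrained:
        raise ValueError("variance decomposition requires a constrained (simplex) fit")
    u = posterior.natural["U"]
    t = posterior.natural["T"]
    b = posterior.natural["B"]
    n = posterior.natural["N"]
    total = u + t + b
    bad = total <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} draws with U+T+B = 0")
        total = np.where(bad, np.nan, total)
    coords = np.stack([u, t, b]) / total  # (3, chains, draws)
    means = tuple(float(np.nanmean(c)) for c in coords)
    chain_means = np.nanmean(coords, axis=2)  # (3, chains)
    n_chains = coords.shape[1]
    sems = tuple(
        float(np.nanstd(cm, ddof=1) / np.sqrt(n_chains)) for cm in chain_means
    )
    return VarianceDecomposition(
        coordinates=means,
        sem=sems,
        technical_noise=float(np.nanmean(n)),
        low_confidence=max(sems) > LOW_CONFIDENCE_SEM,
        lengthscale=float(posterior.natural["lengthscale"].mean()),
    )
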
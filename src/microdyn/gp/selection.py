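"""Greedy model-structure search on evidence ratios.

Starting from the simplest model (all variation technical), each iteration
fits every candidate model that adds exactly one covariance component (each
candidate contains the current model as a special case), and replaces the
current model when the evidence against it exceeds the rejection threshold
(default six bits).  Acceptance is parsimony-first: among candidates that
decisively beat the current model, the one adding the fewest parameters wins
(plain variance components add one parameter; the time-varying components
add a magnitude and a lengthscale), with ties broken by evidence.  Without
this rule the Ornstein-Uhlenbeck component, which degenerates to biological
noise at short lengthscales and to inter-individual differences at long
ones, would absorb both simpler components whenever either is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from microdyn.gp.design import SamplingDesign
from microdyn.gp.evidence import estimate_evidence_bits
from microdyn.gp.kernels import COMPONENT_ORDER, ModelSpec, TECHNICAL
from microdyn.gp.mcmc import PosteriorResult, PriorSpec, run_mcmc

__all__ = ["SelectionResult", "greedy_model_selection"]

#: evidence (chains, samples, burnin, thin) defaults for selection-stage fits
SELECTION_MCMC = dict(chains=5, samples=150, burnin=20, thin=2)


@dataclass
class SelectionResult:
    """Outcome of the greedy search."""

    spec: ModelSpec
    trace: list[dict] = field(default_factory=list)  #: one entry per iteration
    final_fit: PosteriorResult | None = None

    @property
    def components(self) -> frozenset[str]:
        return self.spec.components

    def to_dict(self) -> dict:
        return {
            "selected": sorted(self.spec.components),
            "trace": self.trace,
        }


def greedy_model_selection(
    y: np.ndarray,
    design: SamplingDesign,
    priors: PriorSpec = PriorSpec(),
    threshold_bits: float = 6.0,
    seed: int | None = None,
    candidates: tuple[str, ...] | None = None,
    **mcmc_kwargs,
) -> SelectionResult:
    """Select the covariance component set supported by the data.

    ``candidates`` restricts the components the search may add (default: all
    non-technical components).  MCMC settings for the per-model fits default
    to :data:`SELECTION_MCMC` and can be overridden via keyword arguments.
    Returns the selected :class:`ModelSpec` together with the per-iteration
    evidence trace.
    """
    settings = {**SELECTION_MCMC, **mcmc_kwargs}
    pool = tuple(
        c for c in COMPONENT_ORDER if c != TECHNICAL and (candidates is None or c in candidates)
    )
    seed_seq = np.random.SeedSequence(seed)

    def fit(spec: ModelSpec) -> PosteriorResult:
        child = seed_seq.spawn(1)[0]
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        return run_mcmc(
            y, spec, priors, design, seed=sub_seed, constrained=False, **settings
        )

    current = ModelSpec.null()
    current_fit = fit(current)
    trace: list[dict] = []
    while True:
        remaining = [c for c in pool if c not in current.components]
        if not remaining:
            break
        bits_by_candidate = {}
        fits = {}
        n_params = {}
        for comp in remaining:
            cand = current.with_component(comp)
            cand_fit = fit(cand)
            bits_by_candidate[comp] = estimate_evidence_bits(current_fit, cand_fit)
            fits[comp] = cand_fit
            n_params[comp] = cand.n_params
        # parsimony-first acceptance: among candidates decisively better than
        # the current model, take the one adding the fewest parameters (plain
        # noise components before lengthscale-bearing ones), ties by bits
        decisive = [c for c in remaining if bits_by_candidate[c] > threshold_bits]
        best = None
        if decisive:
            fewest = min(n_params[c] for c in decisive)
            best = max(
                (c for c in decisive if n_params[c] == fewest),
                key=bits_by_candidate.get,
            )
        trace.append(
            {
                "current": sorted(current.components),
                "bits_against_current": {k: float(v) for k, v in bits_by_candidate.items()},
                "best_candidate": best,
                "accepted": best is not None,
            }
        )
        if best is None:
            break
        current = current.with_component(best)
        current_fit = fits[best]
    return SelectionResult(spec=current, trace=trace, final_fit=current_fit)
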
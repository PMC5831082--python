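"""Covariance components, model specifications, and fast likelihood evaluation.

Every component except technical noise is gated by subject identity, so the
covariance matrix is block diagonal by subject.  :class:`GPLikelihood`
exploits this: subjects are grouped by block size and each group's blocks are
factorized with one batched Cholesky, making a likelihood evaluation on an
HMP-scale design (hundreds of samples, <= 6 samples per subject) take tens of
microseconds.  :func:`build_covariance_matrix` builds the equivalent dense
matrix and is the slow reference path used in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from microdyn.gp.design import SamplingDesign

__all__ = [
    "TECHNICAL",
    "BIOLOGICAL_NOISE",
    "INTER_INDIVIDUAL",
    "OU",
    "SQUARED_EXPONENTIAL",
    "PERIODIC_1YR",
    "COMPONENT_ORDER",
    "LENGTHSCALE_COMPONENTS",
    "CANONICAL_COMPONENTS",
    "ModelSpec",
    "GPParams",
    "build_covariance_matrix",
    "GPLikelihood",
]

TECHNICAL = "technical"
BIOLOGICAL_NOISE = "biological_noise"
INTER_INDIVIDUAL = "inter_individual"
OU = "ou"
SQUARED_EXPONENTIAL = "squared_exponential"
PERIODIC_1YR = "periodic_1yr"

COMPONENT_ORDER = (
    TECHNICAL,
    BIOLOGICAL_NOISE,
    INTER_INDIVIDUAL,
    OU,
    SQUARED_EXPONENTIAL,
    PERIODIC_1YR,
)
#: components carrying their own lengthscale parameter (months)
LENGTHSCALE_COMPONENTS = (OU, SQUARED_EXPONENTIAL, PERIODIC_1YR)
#: the constrained variance-decomposition model: U + T + B + N = 1
CANONICAL_COMPONENTS = frozenset({TECHNICAL, BIOLOGICAL_NOISE, INTER_INDIVIDUAL, OU})

PERIOD_MONTHS = 12.0  #: fixed period of the seasonal component
JITTER = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """A model is a set of covariance components; technical noise is always
    included.  Parameter count is one magnitude per component plus one
    lengthscale per time-varying component."""

    components: frozenset[str]

    def __post_init__(self):
        comps = frozenset(self.components) | {TECHNICAL}
        unknown = comps - set(COMPONENT_ORDER)
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")
        object.__setattr__(self, "components", comps)

    @classmethod
    def null(cls) -> "ModelSpec":
        """All variation technical: the greedy search's starting model."""
        return cls(frozenset({TECHNICAL}))

    @classmethod
    def canonical(cls) -> "ModelSpec":
        """The four-component decomposition model (U, T, B, N)."""
        return cls(CANONICAL_COMPONENTS)

    def with_component(self, name: str) -> "ModelSpec":
        return ModelSpec(self.components | {name})

    @property
    def ordered_components(self) -> tuple[str, ...]:
        return tuple(c for c in COMPONENT_ORDER if c in self.components)

    @property
    def lengthscale_components(self) -> tuple[str, ...]:
        return tuple(c for c in LENGTHSCALE_COMPONENTS if c in self.components)

    @property
    def n_params(self) -> int:
        return len(self.components) + len(self.lengthscale_components)

    @property
    def is_canonical(self) -> bool:
        return self.components == CANONICAL_COMPONENTS

    def __str__(self) -> str:
        return "+".join(self.ordered_components)


@dataclass(frozen=True)
class GPParams:
    """Variance components of the constrained model plus the OU lengthscale.

    ``u``, ``t``, ``b``, ``n`` are the inter-individual, time-varying,
    biological-noise and technical-noise variance fractions; a constrained
    fit satisfies u + t + b + n = 1.  ``lengthscale`` is in months.
    """

    u: float
    t: float
    b: float
    n: float
    lengthscale: float

    def __post_init__(self):
        if min(self.u, self.t, self.b, self.n) < 0:
            raise ValueError("variance components must be >= 0")
        if self.lengthscale <= 0:
            raise ValueError("lengthscale must be > 0")

    @property
    def on_simplex(self) -> bool:
        return abs(self.u + self.t + self.b + self.n - 1.0) <= 1e-9

    def magnitudes(self) -> dict[str, float]:
        return {
            TECHNICAL: self.n,
            BIOLOGICAL_NOISE: self.b,
            INTER_INDIVIDUAL: self.u,
            OU: self.t,
        }

    def lengthscales(self) -> dict[str, float]:
        return {OU: self.lengthscale}


def _as_param_dicts(params, spec: ModelSpec):
    if isinstance(params, GPParams):
        return params.magnitudes(), params.lengthscales()
    magnitudes = dict(params[0]) if isinstance(params, tuple) else dict(params)
    lengthscales = dict(params[1]) if isinstance(params, tuple) else {}
    return magnitudes, lengthscales


def _time_kernel(name: str, dt: np.ndarray, lengthscale: float) -> np.ndarray:
    if name == OU:
        return np.exp(-dt / lengthscale)
    if name == SQUARED_EXPONENTIAL:
        return np.exp(-(dt**2) / (2.0 * lengthscale**2))
    if name == PERIODIC_1YR:
        return np.exp(-2.0 * np.sin(np.pi * dt / PERIOD_MONTHS) ** 2 / lengthscale**2)
    raise ValueError(name)


def build_covariance_matrix(
    params,
    spec: ModelSpec,
    design: SamplingDesign,
    check_psd: bool = True,
) -> np.ndarray:
    """Dense covariance matrix for the given parameters and component set.

    ``params`` may be a :class:`GPParams` (canonical model) or a
    ``(magnitudes, lengthscales)`` pair of mappings keyed by component name.
    Raises when the matrix is not positive semi-definite after a jitter of
    :data:`JITTER` on the diagonal.
    """
    magnitudes, lengthscales = _as_param_dicts(params, spec)
    t = design.times_months
    subj = np.asarray(design.subjects, dtype=object)
    spec_ids = np.asarray(design.specimens, dtype=object)
    same_subject = subj[:, None] == subj[None, :]
    same_specimen = spec_ids[:, None] == spec_ids[None, :]
    dt = np.abs(t[:, None] - t[None, :])
    n = design.n
    K = np.zeros((n, n))
    for name in spec.ordered_components:
        mag = magnitudes.get(name, 0.0)
        if mag < 0:
            raise ValueError(f"negative magnitude for {name}")
        if name == TECHNICAL:
            K += mag * np.eye(n)
        elif name == BIOLOGICAL_NOISE:
            K += mag * same_specimen
        elif name == INTER_INDIVIDUAL:
            K += mag * same_subject
        else:
            ls = lengthscales.get(name)
            if ls is None or ls <= 0:
                raise ValueError(f"component {name} requires a positive lengthscale")
            K += mag * _time_kernel(name, dt, ls) * same_subject
    if check_psd:
        try:
            np.linalg.cholesky(K + JITTER * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"covariance not PSD after jitter {JITTER}"
            ) from exc
    return K


class GPLikelihood:
    """Subject-block Gaussian log-likelihood for a fixed design.

    Precomputes, per group of subjects with the same number of samples, the
    stacked time-difference and same-specimen arrays, so each call only
    assembles small batched kernels and runs one batched Cholesky per group.
    """

    def __init__(self, design: SamplingDesign):
        self.design = design
        order: dict[str, list[int]] = {}
        for i, s in enumerate(design.subjects):
            order.setdefault(s, []).append(i)
        by_size: dict[int, list[list[int]]] = {}
        for idx in order.values():
            by_size.setdefault(len(idx), []).append(idx)
        self._groups = []
        t = design.times_months
        specs = np.asarray(design.specimens, dtype=object)
        for m, blocks in sorted(by_size.items()):
            idx = np.array(blocks, dtype=int)  # (g, m)
            tt = t[idx]  # (g, m)
            dt = np.abs(tt[:, :, None] - tt[:, None, :])
            sp = specs[idx]
            same_spec = sp[:, :, None] == sp[:, None, :]
            eye = np.broadcast_to(np.eye(m), (len(blocks), m, m))
            self._groups.append((idx, dt, same_spec.astype(float), eye))
        self.n = design.n

    def loglik(
        self,
        y: np.ndarray,
        magnitudes: Mapping[str, float],
        lengthscales: Mapping[str, float] | None = None,
    ) -> float:
        """Multivariate-normal log density of y under N(0, K(params)).

        Returns ``-inf`` when the covariance is numerically non-PSD for the
        proposed parameters (the MCMC treats that as a rejected state).
        """
        lengthscales = lengthscales or {}
        total = 0.0
        const = np.log(2.0 * np.pi)
        for idx, dt, same_spec, eye in self._groups:
            g, m = idx.shape
            K = np.zeros((g, m, m))
            for name, mag in magnitudes.items():
                if mag == 0.0:
                    continue
                if name == TECHNICAL:
                    K += mag * eye
                elif name == BIOLOGICAL_NOISE:
                    K += mag * same_spec
                elif name == INTER_INDIVIDUAL:
                    K += mag
                else:
                    K += mag * _time_kernel(name, dt, lengthscales[name])
            K += JITTER * eye
            try:
                L = np.linalg.cholesky(K)
            except np.linalg.LinAlgError:
                return -np.inf
            yg = y[idx][..., None]  # (g, m, 1)
            z = np.linalg.solve(L, yg)[..., 0]
            logdiag = np.log(np.diagonal(L, axis1=1, axis2=2))
            total += -0.5 * float((z**2).sum()) - float(logdiag.sum()) - 0.5 * g * m * const
        return total
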
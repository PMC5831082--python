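"""Sample-level ecological QC and the feature-wise variance-stabilization
pipeline applied before Gaussian-process fitting.

Ecological outliers are flagged per body site from each sample's median
Bray-Curtis dissimilarity to all other same-site samples: a sample is an
outlier when its median exceeds the upper inner fence (Q3 + 1.5 IQR) of the
site's medians.  Quartiles use linear interpolation between order statistics
(the "type 7" default), which the fence value depends on.

Feature series destined for GP fitting pass through, in order:
arcsine-square-root transform, iterative two-sided Grubbs outlier removal at
significance 0.05, and standardization to zero mean and unit (sample)
variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from microdyn.io_profiles import AbundanceTable, SampleMetadata

__all__ = [
    "OutlierReport",
    "bray_curtis_dissimilarity",
    "flag_ecological_outliers",
    "arcsine_sqrt_transform",
    "grubbs_outlier_mask",
    "standardize_series",
    "preprocess_feature",
    "prevalence_filter",
    "jaccard_similarity",
]

MIN_SITE_SAMPLES = 4  #: sites with fewer samples are skipped with a warning
GRUBBS_MAX_FRACTION = 0.10  #: guard: at most this fraction of points removable


def bray_curtis_dissimilarity(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity ``1 - 2*sum(min(x, y)) / (sum(x) + sum(y))``.

    Symmetric, in [0, 1] for non-negative vectors; undefined (error) when both
    vectors are all zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum() + y.sum()
    if total == 0:
        raise ValueError("Bray-Curtis undefined: both vectors are all zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


@dataclass
class OutlierReport:
    """Per-site upper-inner-fence outlier screen on median dissimilarities."""

    median_dissimilarity: dict[str, float]  #: per sample id
    site_q3: dict[str, float]
    site_iqr: dict[str, float]
    site_fence: dict[str, float]  #: Q3 + 1.5 * IQR
    flagged: list[str]
    skipped_sites: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "median_dissimilarity": self.median_dissimilarity,
            "site_q3": self.site_q3,
            "site_iqr": self.site_iqr,
            "site_fence": self.site_fence,
            "flagged": sorted(self.flagged),
            "skipped_sites": sorted(self.skipped_sites),
        }


def flag_ecological_outliers(table: AbundanceTable, meta: SampleMetadata) -> OutlierReport:
    """Flag ecologically abnormal samples per body site.

    For every site with at least :data:`MIN_SITE_SAMPLES` samples, computes
    each sample's median Bray-Curtis dissimilarity to all other samples of the
    same site, then flags samples whose median exceeds the site's upper inner
    fence Q3 + 1.5 IQR.  Sites with fewer samples are skipped with a warning.
    Flags are invariant to sample order.
    """
    medians: dict[str, float] = {}
    q3s: dict[str, float] = {}
    iqrs: dict[str, float] = {}
    fences: dict[str, float] = {}
    flagged: list[str] = []
    skipped: list[str] = []
    table_samples = set(table.sample_ids)
    for site in meta.body_sites:
        ids = [s for s in meta.samples_at(site) if s in table_samples]
        ids = sorted(ids)  # order independence
        if len(ids) < MIN_SITE_SAMPLES:
            warnings.warn(f"site {site!r} has {len(ids)} samples (<{MIN_SITE_SAMPLES}); skipped")
            skipped.append(site)
            continue
        vecs = [table.sample_vector(s) for s in ids]
        n = len(ids)
        dmat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dmat[i, j] = dmat[j, i] = bray_curtis_dissimilarity(vecs[i], vecs[j])
        site_medians = np.array(
            [np.median(np.delete(dmat[i], i)) for i in range(n)]
        )
        q1, q3 = np.percentile(site_medians, [25, 75])  # linear interpolation
        iqr = q3 - q1
        fence = q3 + 1.5 * iqr
        q3s[site], iqrs[site], fences[site] = float(q3), float(iqr), float(fence)
        for s, m in zip(ids, site_medians):
            medians[s] = float(m)
            if m > fence:
                flagged.append(s)
    return OutlierReport(medians, q3s, iqrs, fences, sorted(flagged), skipped)


def arcsine_sqrt_transform(x) -> np.ndarray | float:
    """Variance-stabilizing transform ``asin(sqrt(x))`` for fractions.

    Monotone from [0, 1] onto [0, pi/2].  Values outside [0, 1] by more than
    1e-9 raise; values within tolerance are clamped.
    """
    arr = np.asarray(x, dtype=float)
    if (arr < -1e-9).any() or (arr > 1 + 1e-9).any():
        raise ValueError("relative abundance outside [0, 1]")
    out = np.arcsin(np.sqrt(np.clip(arr, 0.0, 1.0)))
    return float(out) if np.isscalar(x) else out


def _grubbs_critical(n: int, alpha: float) -> float:
    # two-sided critical value: G > (n-1)/sqrt(n) * sqrt(t^2 / (n-2+t^2))
    # with t the upper alpha/(2n) quantile of Student-t on n-2 d.f.
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_outlier_mask(values, alpha: float = 0.05) -> np.ndarray:
    """Iterative two-sided Grubbs outlier test.

    Repeatedly removes the single most extreme point while its G statistic
    ``max|x - mean| / sd`` exceeds the critical value at ``alpha``; returns a
    boolean mask marking removed points.  As a guard, at most
    :data:`GRUBBS_MAX_FRACTION` of the points can be removed.  Requires n >= 3.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("Grubbs test requires a 1-d sample with n >= 3")
    mask = np.zeros(x.size, dtype=bool)
    max_removals = max(1, int(np.floor(GRUBBS_MAX_FRACTION * x.size)))
    removed = 0
    while removed < max_removals:
        active = np.where(~mask)[0]
        if active.size < 3:
            break
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        k = int(np.argmax(dev))
        g = dev[k] / sd
        if g <= _grubbs_critical(active.size, alpha):
            break
        mask[active[k]] = True
        removed += 1
    return mask


def standardize_series(values) -> np.ndarray:
    """Center to mean 0 and scale to unit sample (n-1) variance.

    Idempotent and invariant to affine maps ``a*x + b`` with ``a > 0``.
    Raises on zero variance or n < 2.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("standardization requires n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize")
    out = (x - x.mean()) / sd
    return out - out.mean()  # kill residual rounding in the mean


def preprocess_feature(abundances, alpha: float = 0.05):
    """Full pre-GP pipeline: arcsine-sqrt -> Grubbs(alpha) -> standardize.

    Returns ``(values, kept_mask)`` where ``values`` are the standardized
    transformed abundances of the points that survive outlier removal and
    ``kept_mask`` marks the surviving entries of the input.
    """
    transformed = arcsine_sqrt_transform(np.asarray(abundances, dtype=float))
    outliers = grubbs_outlier_mask(transformed, alpha=alpha)
    kept = ~outliers
    return standardize_series(transformed[kept]), kept


def prevalence_filter(
    table: AbundanceTable,
    meta: SampleMetadata,
    site: str,
    prevalence: float = 0.75,
    rescue_mean_abundance: float = 0.02,
    rescue_min_samples: int = 50,
) -> list[str]:
    """Features eligible for dynamics modelling at a site.

    Keeps features non-zero in at least ``prevalence`` of the site's samples,
    with a rescue clause for low-prevalence but high-load features: mean
    abundance when present >= ``rescue_mean_abundance`` and non-zero in at
    least ``rescue_min_samples`` samples.
    """
    ids = [s for s in meta.samples_at(site) if s in set(table.sample_ids)]
    if not ids:
        raise ValueError(f"no samples for site {site!r}")
    sub = table.select_samples(ids)
    vals = sub.values
    nonzero = vals > 0
    counts = nonzero.sum(axis=1)
    prev = counts / len(ids)
    with np.errstate(invalid="ignore"):
        mean_present = np.where(counts > 0, vals.sum(axis=1) / np.maximum(counts, 1), 0.0)
    keep = (prev >= prevalence) | (
        (mean_present >= rescue_mean_abundance) & (counts >= rescue_min_samples)
    )
    return [f for f, k in zip(sub.feature_ids, keep) if k]


def jaccard_similarity(presence_a, presence_b) -> float:
    """Jaccard similarity |A & B| / |A | B| of two presence sets.

    Raises when both sets are empty (similarity undefined).
    """
    a, b = set(presence_a), set(presence_b)
    union = a | b
    if not union:
        raise ValueError("Jaccard undefined: both sets empty")
    return len(a & b) / len(union)
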
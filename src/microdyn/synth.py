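"""Synthetic data with known ground truth for every analysis module.

The generators emulate the longitudinal multi-site study design: up to three
visits per subject with inter-visit gaps roughly uniform between one month
and one year, a configurable technical-replicate rate, zero-inflated
abundance tables, and body-site-structured strain clades.  Every generator
is a pure function of (spec, seed): the same spec gives byte-identical
output, and each output carries a truth record so the analysis modules can
be tested closed-loop without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from microdyn.coreness import DEFAULT_BODY_AREAS
from microdyn.gp.design import MONTHS_PER_DAY, SamplingDesign
from microdyn.gp.kernels import GPParams, ModelSpec, build_covariance_matrix, JITTER
from microdyn.io_profiles import AbundanceTable, SampleMetadata, StrainDistanceMatrix
from microdyn.strain_niche import k2p_distance_matrix

__all__ = [
    "SimulationSpec",
    "SyntheticCommunity",
    "StrainCladeResult",
    "simulate_design",
    "simulate_feature",
    "simulate_abundance_table",
    "simulate_strain_clades",
]

#: default truth mixture: 5% technical noise, remainder split evenly
_EVEN_MIX = GPParams(u=0.95 / 3, t=0.95 / 3, b=0.95 / 3, n=0.05, lengthscale=6.0)


@dataclass(frozen=True)
class SimulationSpec:
    """Study-design and ground-truth settings for all generators.

    ``seed`` is mandatory; generators derive all their randomness from it
    (each generator uses an independent stream spawned from the seed).
    """

    seed: int
    n_subjects: int = 90
    visits_per_subject: int = 3  #: at most 3
    gap_months: tuple[float, float] = (1.0, 12.0)
    replicate_rate: float = 0.15
    true_params: GPParams = field(default_factory=lambda: _EVEN_MIX)
    zero_inflation: float = 0.3
    subjects_per_site: int = 25
    within_site_divergence: float = 0.01  #: expected substitutions/site within a clade
    between_site_divergence: float = 0.5
    sequence_length: int = 500
    transition_transversion_ratio: float = 2.0

    def __post_init__(self):
        if not 1 <= self.visits_per_subject <= 3:
            raise ValueError("visits_per_subject must be 1..3")
        if not 0 <= self.replicate_rate <= 1 or not 0 <= self.zero_inflation < 1:
            raise ValueError("rates must be fractions")
        total = self.true_params.u + self.true_params.t + self.true_params.b + self.true_params.n
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"true mixture must lie on the simplex (sum {total})")

    def with_params(self, params: GPParams) -> "SimulationSpec":
        return replace(self, true_params=params)


def simulate_design(spec: SimulationSpec) -> tuple[SamplingDesign, SampleMetadata]:
    """Longitudinal single-site design: per subject, visit times with gaps
    uniform in ``gap_months``, one specimen per visit, and an extra technical
    replicate per specimen with probability ``replicate_rate``.

    Collection times are drawn in whole days so the design and its metadata
    round-trip exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    lo_days = spec.gap_months[0] / MONTHS_PER_DAY
    hi_days = spec.gap_months[1] / MONTHS_PER_DAY
    rows = []
    for i in range(spec.n_subjects):
        subject = f"S{i:03d}"
        day = 0
        for v in range(spec.visits_per_subject):
            if v > 0:
                day += int(round(rng.uniform(lo_days, hi_days)))
            specimen = f"{subject}.v{v + 1}"
            rows.append((specimen, subject, "stool", day, specimen, v + 1))
            if rng.random() < spec.replicate_rate:
                rows.append((f"{specimen}.rep", subject, "stool", day, specimen, v + 1))
    frame = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "subject_id",
            "body_site",
            "collection_day",
            "replicate_group",
            "visit_number",
        ],
    )
    meta = SampleMetadata(frame)
    return SamplingDesign.from_metadata(meta), meta


def simulate_feature(
    spec: SimulationSpec,
    design: SamplingDesign,
    params: GPParams | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Draw one standardized feature from N(0, K(true params)) on the design.

    ``params`` overrides the spec's truth mixture (e.g. for lengthscale
    sweeps); ``seed`` overrides the derived per-feature seed.  Returns the
    feature vector and a truth record.
    """
    params = params or spec.true_params
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed if seed is None else seed, 1])
    )
    K = build_covariance_matrix(params, ModelSpec.canonical(), design, check_psd=False)
    L = np.linalg.cholesky(K + JITTER * np.eye(design.n))
    y = L @ rng.standard_normal(design.n)
    truth = {
        "U": params.u,
        "T": params.t,
        "B": params.b,
        "N": params.n,
        "lengthscale": params.lengthscale,
    }
    return y, truth


# ---------------------------------------------------------------------------
# multi-site community tables with planted coreness / QC / ecology structure
# ---------------------------------------------------------------------------

HUMAN_GENERA = tuple(f"Hum{c}" for c in "ABCDEFGH")
RARE_GENERA = tuple(f"Rare{c}" for c in "WXYZ")
#: EnvXX genera 0-19 appear in the species table (hence human-associated);
#: 20-39 exist only in annotations (hence non-human-associated)
ENV_IN_TABLE = tuple(f"Env{i:02d}" for i in range(20))
ENV_OUTSIDE = tuple(f"Env{i:02d}" for i in range(20, 40))
COOC_GENERA = ("CoocA", "CoocB")


@dataclass
class SyntheticCommunity:
    """Multi-site abundance tables with planted, recoverable structure."""

    species_table: AbundanceTable
    pathway_table: AbundanceTable
    metadata: SampleMetadata
    annotations: dict[str, set[str]]
    attribution: pd.DataFrame  #: per-sample unclassified copy fraction per pathway
    pangenomes: dict[str, set[str]]
    human_pangenomes: set[str]
    truth: dict


def _site_samples(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for site in sorted(DEFAULT_BODY_AREAS):
        for k in range(spec.subjects_per_site):
            subject = f"{site}.subj{k:02d}"
            specimen = f"{subject}.v1"
            rows.append((specimen, subject, site, 0, specimen, 1))
            if rng.random() < spec.replicate_rate:
                rows.append((f"{specimen}.rep", subject, site, 0, specimen, 1))
            if rng.random() < 0.3:  # some second visits to exercise visit filtering
                day = int(round(rng.uniform(30, 365)))
                spec2 = f"{subject}.v2"
                rows.append((spec2, subject, site, day, spec2, 2))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "subject_id",
            "body_site",
            "collection_day",
            "replicate_group",
            "visit_number",
        ],
    )


def simulate_abundance_table(spec: SimulationSpec) -> SyntheticCommunity:
    """Zero-inflated multi-site species and pathway tables with planted truth.

    Planted structure (all recoverable by the analysis modules, and all
    guaranteed by construction, not merely in expectation):

    * human-associated genera: every genus appearing in the species table is
      forced above 1e-3 relative abundance in >= 5 distinct subjects; the
      RareX genera are capped at 3 subjects and stay below that bar;
    * one co-occurring species pair (present/absent together);
    * one ecological outlier sample per site (a permuted species profile);
    * pathways: a supercore pathway, a two-area multicore pathway, a
      single-site (gut) core pathway, a stool-enriched pathway, one pathway
      excluded by the taxonomic-range filter, one excluded by the
      attribution filter, and a human-microbiome-enriched multicore pathway.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    meta_frame = _site_samples(spec, rng)
    meta = SampleMetadata(meta_frame)
    samples = list(meta_frame["sample_id"])
    sites = np.array(meta_frame["body_site"])
    subjects = list(meta_frame["subject_id"])
    n = len(samples)
    site_list = sorted(DEFAULT_BODY_AREAS)
    subj_unique = sorted(set(subjects))
    cols_of_subject: dict[str, list[int]] = {}
    for j, s in enumerate(subjects):
        cols_of_subject.setdefault(s, []).append(j)

    # ---- species table ----------------------------------------------------
    species_ids: list[str] = []
    blocks: list[np.ndarray] = []

    # background: site-specific mean profiles with a steep rank-abundance
    # curve (lognormal across species, so abundances span orders of
    # magnitude), lognormal per-sample noise, zero inflation; magnitudes
    # normalized so column totals land near 1 before renormalization
    n_background = 30
    site_mean = {}
    for s in site_list:
        base = rng.lognormal(0.0, 1.2, size=n_background)
        site_mean[s] = base / base.sum()
    bg = np.empty((n_background, n))
    for j in range(n):
        base = site_mean[str(sites[j])]
        vals = base * rng.lognormal(0.0, 0.3, size=n_background)
        # zero inflation hits the sub-dominant tail; site-dominant species
        # (>= 5% of the site profile) are consistently present
        drop = (rng.random(n_background) < spec.zero_inflation) & (base < 0.05)
        bg[:, j] = np.where(drop, 0.0, vals)
    for k in range(n_background):
        genus = ENV_IN_TABLE[k % len(ENV_IN_TABLE)]
        species_ids.append(f"g__{genus}.s__bg{k:02d}")
        # force presence for 5 designated subjects so genus-level
        # human-association holds by construction despite zero inflation
        anchors = subj_unique[(3 * k) % len(subj_unique):][:5]
        if len(anchors) < 5:
            anchors = subj_unique[:5]
        for s in anchors:
            for j in cols_of_subject[s]:
                bg[k, j] = max(bg[k, j], rng.uniform(2e-2, 3e-2))
    blocks.append(bg)

    # planted human-associated genera: abundant in 8 designated subjects
    human_rows = []
    for gi, g in enumerate(HUMAN_GENERA):
        hosts = set(rng.choice(subj_unique, size=8, replace=False))
        row = np.zeros(n)
        for j in range(n):
            if subjects[j] in hosts:
                row[j] = rng.uniform(5e-3, 2e-2)
            elif rng.random() < 0.2:
                row[j] = rng.uniform(1e-5, 2e-4)
        human_rows.append(row)
        species_ids.append(f"g__{g}.s__sp1")
    blocks.append(np.array(human_rows))

    # rare genera: above threshold in at most 3 subjects
    rare_rows = []
    for g in RARE_GENERA:
        hosts = set(rng.choice(subj_unique, size=3, replace=False))
        row = np.zeros(n)
        for j in range(n):
            if subjects[j] in hosts:
                row[j] = rng.uniform(5e-3, 1e-2)
        rare_rows.append(row)
        species_ids.append(f"g__{g}.s__sp1")
    blocks.append(np.array(rare_rows))

    # co-occurring pair: present together in ~half the samples
    present = rng.random(n) < 0.5
    # guarantee >= 6 subjects with the pair present and >= 3 without
    for s in subj_unique[:6]:
        present[cols_of_subject[s]] = True
    for s in subj_unique[6:9]:
        present[cols_of_subject[s]] = False
    pair = np.zeros((2, n))
    pair[:, present] = rng.uniform(5e-3, 1e-2, size=(2, int(present.sum())))
    blocks.append(pair)
    species_ids.extend([f"g__{g}.s__one" for g in COOC_GENERA])

    values = np.vstack(blocks)
    values = values / values.sum(axis=0)  # per-sample renormalization

    # ecological outlier: permute one sample's background species values per
    # site (the background carries ~95% of the mass, so the permuted profile
    # is highly atypical; planted rows are left in place so their guarantees
    # survive)
    outliers = []
    for site in site_list:
        cols = [j for j in range(n) if sites[j] == site]
        col = cols[int(rng.integers(len(cols)))]
        values[:n_background, col] = rng.permutation(values[:n_background, col])
        outliers.append(samples[col])

    species = AbundanceTable(pd.DataFrame(values, index=species_ids, columns=samples))

    # ---- pathway table ----------------------------------------------------
    path_rows: dict[str, np.ndarray] = {}
    oral_plus_gut = ("stool", "tongue_dorsum")
    human_enriched_sites = ("buccal_mucosa", "stool", "tongue_dorsum")

    path_rows["PWY_SUPERCORE"] = rng.uniform(5e-4, 2e-3, size=n)
    path_rows["PWY_MULTICORE"] = np.where(
        np.isin(sites, oral_plus_gut), rng.uniform(5e-4, 2e-3, size=n), 0.0
    )
    path_rows["PWY_GUTCORE"] = np.where(
        sites == "stool", rng.uniform(5e-4, 2e-3, size=n), 0.0
    )
    # stool Q1 ~ 8e-3 vs elsewhere Q3 <= 2e-3 (and ~50% prevalence elsewhere,
    # so the pathway is core only at stool)
    elsewhere = np.where(rng.random(n) < 0.5, rng.uniform(2e-4, 2e-3, size=n), 0.0)
    path_rows["PWY_SITE_ENRICHED"] = np.where(
        sites == "stool", rng.uniform(8e-3, 1.2e-2, size=n), elsewhere
    )
    path_rows["PWY_RANGE_FILTERED"] = rng.uniform(5e-4, 2e-3, size=n)
    path_rows["PWY_ATTR_FILTERED"] = rng.uniform(5e-4, 2e-3, size=n)
    path_rows["PWY_HUMAN_ENRICHED"] = np.where(
        np.isin(sites, human_enriched_sites), rng.uniform(5e-4, 2e-3, size=n), 0.0
    )
    for k in range(10):
        row = np.zeros(n)
        mask = rng.random(n) < 0.3
        row[mask] = rng.uniform(2e-4, 1e-3, size=int(mask.sum()))
        path_rows[f"PWY_BG{k:02d}"] = row
    pathway_ids = list(path_rows)
    pathways = AbundanceTable(
        pd.DataFrame(
            np.array([path_rows[p] for p in pathway_ids]), index=pathway_ids, columns=samples
        )
    )

    # ---- annotations / pangenomes / attribution ---------------------------
    human_genera = set(HUMAN_GENERA) | set(ENV_IN_TABLE) | set(COOC_GENERA)
    nonhuman = list(ENV_OUTSIDE)  # 20 genera, the non-human annotation universe
    annotations: dict[str, set[str]] = {
        # broad housekeeping range: most of both universes
        "PWY_SUPERCORE": set(HUMAN_GENERA[:6]) | set(ENV_IN_TABLE) | set(nonhuman),
        "PWY_MULTICORE": set(HUMAN_GENERA) | set(nonhuman[:8]),
        "PWY_GUTCORE": set(HUMAN_GENERA[:2]) | set(nonhuman[:5]),
        "PWY_SITE_ENRICHED": set(HUMAN_GENERA[:2]) | set(nonhuman[:4]),
        "PWY_RANGE_FILTERED": set(nonhuman[:5]),  # no human-associated genus
        "PWY_ATTR_FILTERED": set(HUMAN_GENERA[:2]) | set(nonhuman[:4]),
        "PWY_HUMAN_ENRICHED": set(HUMAN_GENERA[:2]) | {nonhuman[0]},  # 1/20 = 5%
    }
    for k in range(10):
        annotations[f"PWY_BG{k:02d}"] = {HUMAN_GENERA[0]} | set(nonhuman[k:k + 6])

    human_pan = {f"pan_hum{i}" for i in range(10)}
    env_pan = [f"pan_env{i:02d}" for i in range(40)]
    pangenomes: dict[str, set[str]] = {}
    for p in pathway_ids:
        if p == "PWY_HUMAN_ENRICHED":
            pangenomes[p] = set(sorted(human_pan)[:3]) | set(env_pan[:2])  # 2/40 = 5%
        elif p == "PWY_SUPERCORE":
            pangenomes[p] = human_pan | set(env_pan)  # anchors the universe
        else:
            pangenomes[p] = set(sorted(human_pan)[:2]) | set(env_pan[:6])

    attribution = pd.DataFrame(
        rng.uniform(0.0, 0.2, size=(len(pathway_ids), n)),
        index=pathway_ids,
        columns=samples,
    )
    # 40% of each site's subjects get dominantly unclassified attribution for
    # the planted pathway, so any subject-balanced sample subset exceeds the
    # 25%-of-samples bar
    for site in site_list:
        site_subjects = sorted({s for s, st in zip(subjects, sites) if st == site})
        chosen = site_subjects[: max(1, int(np.ceil(0.4 * len(site_subjects))))]
        cols = [samples[j] for s in chosen for j in cols_of_subject[s]]
        attribution.loc["PWY_ATTR_FILTERED", cols] = rng.uniform(0.55, 0.9, size=len(cols))

    truth = {
        "human_genera": human_genera,
        "rare_genera": set(RARE_GENERA),
        "cooccurring_pair": tuple(f"g__{g}.s__one" for g in COOC_GENERA),
        "outlier_samples": outliers,
        "supercore": ["PWY_SUPERCORE"],
        "multicore": ["PWY_HUMAN_ENRICHED", "PWY_MULTICORE", "PWY_SUPERCORE"],
        "single_site_core": {"PWY_GUTCORE": "stool", "PWY_SITE_ENRICHED": "stool"},
        "site_enriched": {"stool": ["PWY_SITE_ENRICHED"]},
        "human_enriched": ["PWY_HUMAN_ENRICHED"],
        "excluded": {"PWY_RANGE_FILTERED": "range", "PWY_ATTR_FILTERED": "attribution"},
    }
    return SyntheticCommunity(
        species_table=species,
        pathway_table=pathways,
        metadata=meta,
        annotations=annotations,
        attribution=attribution,
        pangenomes=pangenomes,
        human_pangenomes=human_pan,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# site-structured strain clades
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _mutate(seq: np.ndarray, rate: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Independent-site substitution with transition/transversion ratio kappa."""
    out = seq.copy()
    hits = np.where(rng.random(seq.size) < rate)[0]
    p_transition = kappa / (kappa + 1.0)
    for i in hits:
        base = out[i]
        if rng.random() < p_transition:
            out[i] = _TRANSITION[base]
        else:
            out[i] = _TRANSVERSIONS[base][int(rng.integers(2))]
    return out


@dataclass
class StrainCladeResult:
    """Haplotype alignment with site-structured (or null) clades."""

    alignment: dict[str, str]
    fasta: str
    distance_matrix: StrainDistanceMatrix
    site_of: dict[str, str]
    structured: bool


def simulate_strain_clades(
    spec: SimulationSpec,
    sites: Sequence[str] = ("buccal_mucosa", "tongue_dorsum"),
    samples_per_site: int = 8,
    structured: bool = True,
) -> StrainCladeResult:
    """Haplotypes mutated from per-site ancestors (between-site divergence
    much larger than within-site), plus the K2P distance matrix and truth.

    With ``structured=False`` all haplotypes descend from a single shared
    ancestor at the within-site rate: the niche-association null.
    """
    if len(sites) < 2 or samples_per_site < 5:
        raise ValueError("need >= 2 sites and >= 5 samples per site")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    kappa = spec.transition_transversion_ratio
    root = _BASES[rng.integers(4, size=spec.sequence_length)]
    alignment: dict[str, str] = {}
    site_of: dict[str, str] = {}
    for site in sites:
        if structured:
            ancestor = _mutate(root, spec.between_site_divergence / 2.0, kappa, rng)
        else:
            ancestor = root
        for k in range(samples_per_site):
            hap = _mutate(ancestor, spec.within_site_divergence / 2.0, kappa, rng)
            name = f"{site}.h{k:02d}"
            alignment[name] = "".join(hap)
            site_of[name] = site
    fasta = "".join(f">{name}\n{seq}\n" for name, seq in alignment.items())
    dm = k2p_distance_matrix(alignment, site_of)
    return StrainCladeResult(alignment, fasta, dm, site_of, structured)
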
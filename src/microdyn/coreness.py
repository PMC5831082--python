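"""Core-pathway classification for multi-site metagenomic function profiles.

A pathway is *core* to a body site when it is detected (relative abundance
strictly above a detection threshold, default 1e-4) in at least 75% of
subject-unique samples at that site, and survives two taxonomic filters:
its annotated taxonomic range must include at least one human-associated
genus, and it must not have predominantly unclassified taxonomic attribution
(>50% of copies unclassified in >25% of samples).  Pathways core to sites in
two or more body areas are *multicore*; pathways core to all targeted sites
are *supercore*.  Additional calls: human-microbiome enrichment (annotated to
<10% of non-human-associated genera and pangenomes), body-site enrichment
(first quartile at the focal site more than twice the third quartile at every
site of a different body area), an essential-gene prevalence summary, and a
presence/absence co-occurrence screen (Fisher's exact test, BH FDR).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from microdyn.io_profiles import AbundanceTable, SampleMetadata

__all__ = [
    "CorenessConfig",
    "CorenessReport",
    "CoOccurrenceResult",
    "PrevalenceSummary",
    "select_subject_unique_samples",
    "detect_core_pathways",
    "human_associated_genera",
    "apply_taxonomic_filters",
    "classify_core_levels",
    "classify_coreness",
    "taxonomic_range_fraction",
    "human_enriched_flag",
    "site_enriched_flag",
    "prevalence_and_coreness_counts",
    "co_occurrence_screen",
    "genus_of",
]

#: the six targeted body sites grouped into body areas
DEFAULT_BODY_AREAS: dict[str, str] = {
    "anterior_nares": "nasal",
    "buccal_mucosa": "oral",
    "supragingival_plaque": "oral",
    "tongue_dorsum": "oral",
    "stool": "gut",
    "posterior_fornix": "vaginal",
}


@dataclass(frozen=True)
class CorenessConfig:
    """All thresholds of the core-pathway procedure."""

    detection_threshold: float = 1e-4  #: strict > for "detected"
    prevalence_threshold: float = 0.75  #: >= for "core"
    human_min_subjects: int = 5  #: subjects needed for a human-associated genus
    human_detection_threshold: float = 1e-3
    attribution_copy_fraction: float = 0.5  #: unclassified copies per sample, strict >
    attribution_sample_fraction: float = 0.25  #: fraction of samples, strict >
    enrichment_max_fraction: float = 0.10  #: strict < for human-enriched
    site_enrichment_ratio: float = 2.0  #: Q1 focal > ratio * Q3 elsewhere
    body_area_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_BODY_AREAS)
    )

    def __post_init__(self):
        for name in ("detection_threshold", "prevalence_threshold",
                     "attribution_copy_fraction", "attribution_sample_fraction",
                     "enrichment_max_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if self.site_enrichment_ratio <= 0 or self.human_min_subjects < 1:
            raise ValueError("thresholds must be positive")

    @property
    def targeted_sites(self) -> list[str]:
        return sorted(self.body_area_map)


def genus_of(feature_id: str) -> str:
    """Genus of a species-level feature id.

    Understands MetaPhlAn-style ids containing ``g__Genus`` segments; falls
    back to the first whitespace/underscore-delimited token.
    """
    if "g__" in feature_id:
        tail = feature_id.split("g__", 1)[1]
        for sep in (".", "|", ";"):
            tail = tail.split(sep)[0]
        return tail
    return feature_id.replace("_", " ").split()[0]


def select_subject_unique_samples(meta: SampleMetadata) -> list[str]:
    """One sample per (subject, body site): the lowest visit number, with the
    first technical replicate kept by stable input order.  Returned in the
    metadata's row order."""
    frame = meta.frame
    keep: list[str] = []
    for _, sub in frame.groupby(["subject_id", "body_site"], sort=False):
        first = sub[sub["visit_number"] == sub["visit_number"].min()]
        keep.append(first["sample_id"].iloc[0])
    order = {s: i for i, s in enumerate(frame["sample_id"])}
    return sorted(keep, key=order.__getitem__)


def detect_core_pathways(
    table: AbundanceTable, meta: SampleMetadata, cfg: CorenessConfig = CorenessConfig()
) -> dict[str, set[str]]:
    """Per-site core candidates: pathways with abundance strictly above the
    detection threshold in at least ``prevalence_threshold`` of the site's
    subject-unique samples.  Sites without subject-unique samples in the
    table are skipped."""
    unique = [s for s in select_subject_unique_samples(meta) if s in set(table.sample_ids)]
    site_of = meta.site_of()
    candidates: dict[str, set[str]] = {}
    for site in meta.body_sites:
        ids = [s for s in unique if site_of[s] == site]
        if not ids:
            continue
        sub = table.select_samples(ids)
        detected = sub.values > cfg.detection_threshold
        frac = detected.mean(axis=1)
        candidates[site] = {
            f for f, p in zip(sub.feature_ids, frac) if p >= cfg.prevalence_threshold
        }
    return candidates


def human_associated_genera(
    species_table: AbundanceTable,
    meta: SampleMetadata,
    cfg: CorenessConfig = CorenessConfig(),
    genus_map: Mapping[str, str] | None = None,
) -> set[str]:
    """Genera detected above the human-association threshold in at least
    ``human_min_subjects`` distinct subjects."""
    lookup = genus_map if genus_map is not None else {
        f: genus_of(f) for f in species_table.feature_ids
    }
    frame = meta.frame
    subject_of = dict(zip(frame["sample_id"], frame["subject_id"]))
    genus_subjects: dict[str, set[str]] = {}
    vals = species_table.values
    for i, feat in enumerate(species_table.feature_ids):
        genus = lookup[feat]
        for j, sample in enumerate(species_table.sample_ids):
            if sample in subject_of and vals[i, j] > cfg.human_detection_threshold:
                genus_subjects.setdefault(genus, set()).add(subject_of[sample])
    return {
        g for g, subs in genus_subjects.items() if len(subs) >= cfg.human_min_subjects
    }


def apply_taxonomic_filters(
    candidates: Mapping[str, set[str]],
    annotations: Mapping[str, Iterable[str]],
    attribution_table: AbundanceTable | pd.DataFrame | None,
    human_genera: set[str],
    cfg: CorenessConfig = CorenessConfig(),
    samples_by_site: Mapping[str, Iterable[str]] | None = None,
) -> tuple[dict[str, set[str]], dict[str, dict[str, str]]]:
    """Apply the taxonomic-range and unclassified-attribution filters.

    ``annotations`` maps pathway -> annotated genus set; ``attribution_table``
    gives per-sample fraction of pathway copies with unclassified taxonomy
    (pathways x samples; ``None`` disables the attribution filter).  A
    candidate is excluded when its range includes no human-associated genus
    (reasons ``"no annotation"`` / ``"range"``) or when the unclassified
    fraction exceeds the copy threshold in more than the sample-fraction
    threshold of samples (reason ``"attribution"``).  Returns the filtered
    per-site core sets and per-site exclusion reasons.
    """
    if isinstance(attribution_table, AbundanceTable):
        attribution = attribution_table.to_frame()
    else:
        attribution = attribution_table
    core: dict[str, set[str]] = {}
    excluded: dict[str, dict[str, str]] = {}
    for site, paths in candidates.items():
        core[site] = set()
        excluded[site] = {}
        if attribution is not None:
            if samples_by_site is not None:
                cols = [s for s in samples_by_site[site] if s in attribution.columns]
            else:
                cols = list(attribution.columns)
        for p in paths:
            if p not in annotations:
                excluded[site][p] = "no annotation"
                continue
            if not set(annotations[p]) & human_genera:
                excluded[site][p] = "range"
                continue
            if attribution is not None and p in attribution.index and cols:
                frac = attribution.loc[p, cols].to_numpy(dtype=float)
                share = (frac > cfg.attribution_copy_fraction).mean()
                if share > cfg.attribution_sample_fraction:
                    excluded[site][p] = "attribution"
                    continue
            core[site].add(p)
    return core, excluded


@dataclass
class CorenessReport:
    """Classification of every pathway across sites.

    ``level`` per pathway is one of ``none`` (core nowhere), ``core``,
    ``multicore`` (core in >= 2 body areas) or ``supercore`` (core at every
    targeted site); the levels nest, and ``level`` reports the highest.
    """

    core_sets: dict[str, set[str]]
    sites_core_at: dict[str, list[str]]
    level: dict[str, str]
    exclusions: dict[str, dict[str, str]] = field(default_factory=dict)
    range_fractions: dict[str, tuple[float, float]] = field(default_factory=dict)
    human_enriched: dict[str, bool] = field(default_factory=dict)
    site_enriched: dict[str, list[str]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        levels = list(self.level.values())
        n_core = sum(lv in ("core", "multicore", "supercore") for lv in levels)
        n_multi = sum(lv in ("multicore", "supercore") for lv in levels)
        n_super = sum(lv == "supercore" for lv in levels)
        instances = sum(len(s) for s in self.core_sets.values())
        return {
            "core_instances": instances,
            "core_pathways": n_core,
            "multicore_pathways": n_multi,
            "supercore_pathways": n_super,
        }

    def to_dict(self) -> dict:
        return {
            "core_sets": {s: sorted(v) for s, v in self.core_sets.items()},
            "sites_core_at": self.sites_core_at,
            "level": self.level,
            "counts": self.counts(),
            "exclusions": self.exclusions,
            "range_fractions": {p: list(v) for p, v in self.range_fractions.items()},
            "human_enriched": self.human_enriched,
            "site_enriched": self.site_enriched,
        }


def classify_core_levels(
    core_sets: Mapping[str, set[str]], cfg: CorenessConfig = CorenessConfig()
) -> CorenessReport:
    """Assign core / multicore / supercore levels from filtered per-site core
    sets.  Supercore requires coreness at all targeted sites; multicore
    requires sites from at least two body areas."""
    targeted = set(cfg.targeted_sites)
    pathways = sorted(set().union(*core_sets.values())) if core_sets else []
    sites_core_at: dict[str, list[str]] = {}
    level: dict[str, str] = {}
    for p in pathways:
        sites = sorted(s for s, members in core_sets.items() if p in members)
        sites_core_at[p] = sites
        areas = {cfg.body_area_map.get(s, s) for s in sites}
        if targeted and targeted <= set(sites):
            level[p] = "supercore"
        elif len(areas) >= 2:
            level[p] = "multicore"
        elif sites:
            level[p] = "core"
        else:
            level[p] = "none"
    return CorenessReport(
        core_sets={s: set(v) for s, v in core_sets.items()},
        sites_core_at=sites_core_at,
        level=level,
    )


def taxonomic_range_fraction(
    pathway: str,
    annotations: Mapping[str, Iterable[str]],
    human_genera: set[str],
) -> tuple[float, float]:
    """Fractions of the human-associated and non-human-associated genus
    universes to which a pathway is annotated.  The universe is the union of
    all genera in the annotation table; empty sub-universes contribute 0."""
    universe = set()
    for genera in annotations.values():
        universe |= set(genera)
    if not universe:
        raise ValueError("empty genus universe")
    annotated = set(annotations.get(pathway, ()))
    human_universe = universe & human_genera
    nonhuman_universe = universe - human_genera
    human_frac = len(annotated & human_universe) / len(human_universe) if human_universe else 0.0
    nonhuman_frac = (
        len(annotated & nonhuman_universe) / len(nonhuman_universe)
        if nonhuman_universe
        else 0.0
    )
    return human_frac, nonhuman_frac


def human_enriched_flag(
    pathway: str,
    annotations: Mapping[str, Iterable[str]],
    pangenome_table: Mapping[str, Iterable[str]],
    human_genera: set[str],
    human_pangenomes: set[str],
    cfg: CorenessConfig = CorenessConfig(),
) -> bool:
    """True when the pathway is annotated to strictly less than the
    enrichment threshold of non-human-associated genera (annotation source)
    *and* of non-human-associated pangenomes (profiler database source)."""
    _, nonhuman_annot = taxonomic_range_fraction(pathway, annotations, human_genera)
    _, nonhuman_pan = taxonomic_range_fraction(pathway, pangenome_table, human_pangenomes)
    t = cfg.enrichment_max_fraction
    return nonhuman_annot < t and nonhuman_pan < t


def site_enriched_flag(
    pathway: str,
    site: str,
    table: AbundanceTable,
    meta: SampleMetadata,
    cfg: CorenessConfig = CorenessConfig(),
) -> bool:
    """True when the pathway's first abundance quartile at the focal site
    exceeds ``site_enrichment_ratio`` times its third quartile at every site
    belonging to a different body area (sites of the same area, e.g. other
    oral sites, are not required to separate)."""
    unique = [s for s in select_subject_unique_samples(meta) if s in set(table.sample_ids)]
    site_of = meta.site_of()
    focal_area = cfg.body_area_map.get(site, site)
    focal_ids = [s for s in unique if site_of[s] == site]
    if not focal_ids:
        raise ValueError(f"no subject-unique samples at {site!r}")
    row = dict(zip(table.sample_ids, table.feature_vector(pathway)))
    q1_focal = float(np.percentile([row[s] for s in focal_ids], 25))
    for other in meta.body_sites:
        if cfg.body_area_map.get(other, other) == focal_area:
            continue
        ids = [s for s in unique if site_of[s] == other]
        if not ids:
            continue
        q3 = float(np.percentile([row[s] for s in ids], 75))
        if not q1_focal > cfg.site_enrichment_ratio * q3:
            return False
    return True


def classify_coreness(
    pathway_table: AbundanceTable,
    species_table: AbundanceTable,
    meta: SampleMetadata,
    annotations: Mapping[str, Iterable[str]],
    attribution_table: AbundanceTable | pd.DataFrame | None = None,
    pangenome_table: Mapping[str, Iterable[str]] | None = None,
    human_pangenomes: set[str] | None = None,
    cfg: CorenessConfig = CorenessConfig(),
) -> CorenessReport:
    """The full classification pipeline in one call.

    Detects per-site core candidates on subject-unique samples, derives the
    human-associated genus set from the species table, applies both
    taxonomic filters, assigns core/multicore/supercore levels, and — when
    annotation sources allow — computes taxonomic-range fractions,
    human-enrichment flags (multicore pathways only) and per-site
    site-enrichment flags.
    """
    human = human_associated_genera(species_table, meta, cfg)
    candidates = detect_core_pathways(pathway_table, meta, cfg)
    unique = select_subject_unique_samples(meta)
    site_of = meta.site_of()
    samples_by_site = {
        site: [s for s in unique if site_of[s] == site] for site in candidates
    }
    core_sets, exclusions = apply_taxonomic_filters(
        candidates, annotations, attribution_table, human, cfg, samples_by_site
    )
    report = classify_core_levels(core_sets, cfg)
    report.exclusions = exclusions
    for p in report.level:
        report.range_fractions[p] = taxonomic_range_fraction(p, annotations, human)
    if pangenome_table is not None and human_pangenomes is not None:
        for p, lv in report.level.items():
            if lv in ("multicore", "supercore"):
                report.human_enriched[p] = human_enriched_flag(
                    p, annotations, pangenome_table, human, human_pangenomes, cfg
                )
    for p, sites in report.sites_core_at.items():
        enriched = [
            s for s in sites if site_enriched_flag(p, s, pathway_table, meta, cfg)
        ]
        if enriched:
            report.site_enriched[p] = enriched
    return report


@dataclass
class PrevalenceSummary:
    """Global prevalence and per-site coreness by essentiality class."""

    median_prevalence: dict[str, float]
    mean_sites_core: dict[str, float]
    p_prevalence: float
    p_sites_core: float
    n_per_class: dict[str, int]


def prevalence_and_coreness_counts(
    feature_table: AbundanceTable,
    meta: SampleMetadata,
    essential_ids: Iterable[str],
    cfg: CorenessConfig = CorenessConfig(),
) -> PrevalenceSummary:
    """Compare essential vs non-essential gene families on global prevalence
    (fraction of subject-unique samples with abundance above the detection
    threshold) and the number of sites at which each family is core
    (within-site prevalence above the coreness threshold).  Class differences
    are tested with two-sided Wilcoxon rank-sum tests."""
    essential = set(essential_ids)
    unique = [s for s in select_subject_unique_samples(meta) if s in set(feature_table.sample_ids)]
    if not unique:
        raise ValueError("no subject-unique samples available")
    sub = feature_table.select_samples(unique)
    site_of = meta.site_of()
    detected = sub.values > cfg.detection_threshold
    prevalence = detected.mean(axis=1)
    sites = sorted({site_of[s] for s in unique})
    cols_by_site = {
        site: [k for k, s in enumerate(unique) if site_of[s] == site] for site in sites
    }
    sites_core = np.zeros(len(sub.feature_ids))
    for site, cols in cols_by_site.items():
        frac = detected[:, cols].mean(axis=1)
        sites_core += frac > cfg.prevalence_threshold
    is_ess = np.array([f in essential for f in sub.feature_ids])
    if not is_ess.any() or is_ess.all():
        raise ValueError("both essentiality classes must be non-empty")
    out_prev, out_core, n = {}, {}, {}
    for name, m in (("essential", is_ess), ("non_essential", ~is_ess)):
        out_prev[name] = float(np.median(prevalence[m]))
        out_core[name] = float(np.mean(sites_core[m]))
        n[name] = int(m.sum())
    p_prev = float(stats.ranksums(prevalence[is_ess], prevalence[~is_ess]).pvalue)
    p_core = float(stats.ranksums(sites_core[is_ess], sites_core[~is_ess]).pvalue)
    return PrevalenceSummary(out_prev, out_core, p_prev, p_core, n)


@dataclass
class CoOccurrenceResult:
    """Pairwise presence/absence association screen."""

    table: pd.DataFrame  #: one row per tested unordered pair
    skipped: list[tuple[str, str, str]]  #: (a, b, reason)
    threshold: float
    fdr: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["q"] < self.fdr].reset_index(drop=True)


def co_occurrence_screen(
    species_table: AbundanceTable,
    threshold: float = 1e-3,
    fdr: float = 0.1,
) -> CoOccurrenceResult:
    """Fisher's exact co-occurrence screen on presence/absence calls.

    Features are binarized at ``threshold`` relative abundance; every
    unordered feature pair gets a two-sided Fisher's exact test on its 2x2
    presence table, and Benjamini-Hochberg q-values are computed across the
    tested pairs.  Pairs where either feature is constant after binarization
    are skipped with a reason.
    """
    present = species_table.values > threshold
    ids = species_table.feature_ids
    if len(ids) < 2:
        raise ValueError("co-occurrence screen needs >= 2 features")
    rows = []
    skipped: list[tuple[str, str, str]] = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        a, b = present[i], present[j]
        if a.all() or not a.any():
            skipped.append((ids[i], ids[j], f"{ids[i]} constant"))
            continue
        if b.all() or not b.any():
            skipped.append((ids[i], ids[j], f"{ids[j]} constant"))
            continue
        n11 = int(np.sum(a & b))
        n10 = int(np.sum(a & ~b))
        n01 = int(np.sum(~a & b))
        n00 = int(np.sum(~a & ~b))
        odds, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
        rows.append((ids[i], ids[j], n11, n10, n01, n00, float(odds), float(p)))
    frame = pd.DataFrame(
        rows, columns=["feature_a", "feature_b", "n11", "n10", "n01", "n00", "odds_ratio", "p"]
    )
    if len(frame):
        frame["q"] = stats.false_discovery_control(frame["p"], method="bh")
    else:
        frame["q"] = pd.Series(dtype=float)
    return CoOccurrenceResult(frame, skipped, threshold, fdr)
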
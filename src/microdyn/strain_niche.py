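"""Strain-level niche association and reference-genome coverage.

Strain divergence is measured by the Kimura two-parameter (K2P) distance,
which separates transition and transversion fractions.  Body-site structure
of strains is quantified by a silhouette-style directed dissimilarity
``D(u, v)`` between sites and summarized per species by the niche-association
score ``A`` (the maximum D over eligible directed site pairs).  Coverage of
observed strains by reference genomes is scored as one minus the asymmetric
unique-fraction phylogenetic distance (UniFrac G).

The exact D(u, v) construction: with ``a(u)`` the mean K2P distance over
unordered pairs of strains within site u and ``b(u, v)`` the mean distance
between strains of u and strains of v,

    D(u, v) = (b(u, v) - a(u)) / max(b(u, v), a(u)),

an asymmetric analogue of the silhouette width built from site-level means.
D is 1 for perfectly separated sites, 0 when cross-site divergence equals
within-site divergence, and negative when strains are closer to the other
site than to their own.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from microdyn.io_profiles import StrainDistanceMatrix, ValidationError

__all__ = [
    "kimura_2p_distance",
    "k2p_distance_matrix",
    "site_dissimilarity_D",
    "NicheScoreResult",
    "niche_association_score",
    "RootedTree",
    "reference_coverage",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


class SaturationError(ValueError):
    """The K2P log argument is non-positive: distance undefined (saturation)."""


def kimura_2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance between two aligned nucleotide sequences.

    With P and Q the transition and transversion fractions over positions
    where both sequences have an unambiguous A/C/G/T base,

        d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))   [substitutions/site]

    Gap and ambiguity positions are excluded pairwise.  Raises
    :class:`SaturationError` when a log argument is non-positive, and
    ``ValueError`` when no comparable positions remain.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = seq_a.upper()
    b = seq_b.upper()
    compared = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        compared += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if compared == 0:
        raise ValueError("no comparable positions (all gaps/ambiguous)")
    P = transitions / compared
    Q = transversions / compared
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"distance undefined (saturation): P={P:.4g}, Q={Q:.4g}"
        )
    return float(-0.5 * np.log(w1 * np.sqrt(w2)))


def k2p_distance_matrix(
    alignment: Mapping[str, str], site_map: Mapping[str, str] | None = None
) -> StrainDistanceMatrix:
    """Pairwise K2P distances for an aligned set of haplotypes.

    ``site_map`` attaches a body-site label per sequence id (required by the
    niche score); ids missing a label raise.  Without a map, all samples get
    the placeholder site ``"unassigned"``.
    """
    ids = list(alignment)
    if site_map is not None:
        missing = [s for s in ids if s not in site_map]
        if missing:
            raise ValidationError(f"samples missing from site map: {missing}")
        sites = tuple(site_map[s] for s in ids)
    else:
        sites = tuple("unassigned" for _ in ids)
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = kimura_2p_distance(
                alignment[ids[i]], alignment[ids[j]]
            )
    return StrainDistanceMatrix(tuple(ids), sites, values)


def _within_mean(values: np.ndarray, idx: np.ndarray) -> float:
    """Mean distance over unordered pairs within ``idx`` (requires >= 2)."""
    sub = values[np.ix_(idx, idx)]
    n = len(idx)
    return float(sub[np.triu_indices(n, k=1)].mean())


def site_dissimilarity_D(dm: StrainDistanceMatrix, u: str, v: str) -> float:
    """Directed silhouette-style dissimilarity between body sites u and v.

    ``(b(u,v) - a(u)) / max(b(u,v), a(u))`` with a(u) the mean within-u
    distance (unordered pairs) and b(u,v) the mean u-to-v distance.  Defined
    as 0 when all involved distances are zero.  Asymmetric in (u, v).
    """
    iu = dm.indices_in_site(u)
    iv = dm.indices_in_site(v)
    if len(iu) < 2:
        raise ValueError(f"site {u!r} needs >= 2 samples for the within-site mean")
    if len(iv) < 1:
        raise ValueError(f"site {v!r} has no samples")
    a = _within_mean(dm.values, iu)
    b = float(dm.values[np.ix_(iu, iv)].mean())
    denom = max(a, b)
    if denom == 0:
        return 0.0
    return (b - a) / denom


@dataclass
class NicheScoreResult:
    """Niche-association score for one species.

    ``score`` is the maximum D(u, v) over all directed pairs of eligible
    sites (sites with at least ``min_samples`` strains); ``argmax_pairs``
    lists every directed pair attaining it.
    """

    score: float
    pair_scores: dict[tuple[str, str], float]
    site_sizes: dict[str, int]
    eligible_sites: list[str]
    argmax_pairs: list[tuple[str, str]] = field(default_factory=list)
    species_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "score": self.score,
            "eligible_sites": self.eligible_sites,
            "site_sizes": self.site_sizes,
            "pair_scores": {f"{u}|{v}": s for (u, v), s in self.pair_scores.items()},
            "argmax_pairs": [list(p) for p in self.argmax_pairs],
        }


def niche_association_score(
    dm: StrainDistanceMatrix, min_samples: int = 5, species_id: str | None = None
) -> NicheScoreResult:
    """Niche-association score A = max over directed eligible site pairs of
    D(u, v); a pair is eligible when both sites hold at least ``min_samples``
    strains.  Raises when fewer than two sites are eligible."""
    sizes = {site: len(dm.indices_in_site(site)) for site in dm.sites}
    eligible = sorted(s for s, n in sizes.items() if n >= min_samples)
    if len(eligible) < 2:
        raise ValueError(
            f"score undefined: {len(eligible)} site(s) with >= {min_samples} samples"
        )
    pair_scores: dict[tuple[str, str], float] = {}
    for u, v in itertools.permutations(eligible, 2):
        pair_scores[(u, v)] = site_dissimilarity_D(dm, u, v)
    score = max(pair_scores.values())
    argmax = [p for p, s in pair_scores.items() if s == score]
    return NicheScoreResult(
        score=float(score),
        pair_scores=pair_scores,
        site_sizes=sizes,
        eligible_sites=eligible,
        argmax_pairs=argmax,
        species_id=species_id,
    )


class RootedTree:
    """Rooted phylogeny whose leaves are partitioned into metagenome-strain
    leaves and reference-genome leaves.

    Thin wrapper over a dendropy tree; branch lengths are substitutions/site
    (missing lengths are treated as 0) and must be non-negative.
    """

    def __init__(self, tree, strain_leaves: Iterable[str], reference_leaves: Iterable[str]):
        self.tree = tree
        self.strain_leaves = frozenset(strain_leaves)
        self.reference_leaves = frozenset(reference_leaves)
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValidationError("tree contains an unlabeled leaf")
            labels.append(leaf.taxon.label)
        label_set = set(labels)
        if len(labels) != len(label_set):
            raise ValidationError("duplicate leaf labels")
        if self.strain_leaves & self.reference_leaves:
            raise ValidationError("a leaf cannot be both strain and reference")
        uncovered = label_set - self.strain_leaves - self.reference_leaves
        if uncovered:
            raise ValidationError(f"leaves not assigned to a partition: {sorted(uncovered)}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")

    @classmethod
    def from_newick(
        cls,
        newick: str,
        strain_leaves: Sequence[str],
        reference_leaves: Sequence[str],
    ) -> "RootedTree":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        return cls(tree, strain_leaves, reference_leaves)

    def branch_partition(self) -> list[tuple[float, frozenset[str]]]:
        """(length, descendant-leaf-label set) per branch, root edge excluded."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue  # root edge carries no information
            length = node.edge.length or 0.0
            below = frozenset(
                leaf.taxon.label for leaf in node.leaf_iter()
            )
            out.append((float(length), below))
        return out


def reference_coverage(tree: RootedTree) -> float:
    """Reference-genome coverage of observed strains: ``1 - UniFrac G``.

    UniFrac G is the strain-normalized unique fraction: the total length of
    branches whose descendant leaves are exclusively strains, divided by the
    total length of branches ancestral to at least one strain leaf.  Coverage
    is 1 when every strain sits on a zero-length branch next to a reference
    and decreases as strain diversity becomes private to the strain set.
    """
    if not tree.strain_leaves:
        raise ValueError("tree has no strain leaves")
    if not tree.reference_leaves:
        raise ValueError("tree has no reference leaves")
    strains = tree.strain_leaves
    ancestral = exclusive = 0.0
    for length, below in tree.branch_partition():
        touched = below & strains
        if touched:
            ancestral += length
            if below <= strains:
                exclusive += length
    if ancestral == 0:
        raise ValueError("zero total strain-ancestral branch length")
    return 1.0 - exclusive / ancestral
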
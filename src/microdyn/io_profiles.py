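"""Validated containers and TSV/FASTA readers and writers.

All tabular formats are tab-separated UTF-8 text with ``#`` comment lines and
``.`` decimal points, matching the conventions of common taxonomic and
functional profilers.  Validation is strict and loud: tables are never
silently renormalized or symmetrized; an explicit method exists for every
mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "AbundanceTable",
    "SampleMetadata",
    "StrainDistanceMatrix",
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_annotation_table",
    "write_annotation_table",
    "read_fasta_alignment",
]

COLUMN_SUM_TOL = 1e-6
SYMMETRY_TOL = 1e-9

#: columns required in a sample metadata TSV
METADATA_COLUMNS = ("sample_id", "subject_id", "body_site", "collection_day", "replicate_group")


class ValidationError(ValueError):
    """An input violated a structural invariant (negative abundance,
    duplicated identifier, inconsistent replicate group, asymmetry, ...)."""


def _check_unique(ids: Sequence, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


class AbundanceTable:
    """Feature-by-sample relative abundance matrix.

    Rows are features (species or pathways), columns are samples, values are
    unitless fractions in [0, 1].  Column sums may be below 1 (unnormalized
    pathway tables are accepted); :meth:`renormalize` rescales explicitly.
    """

    def __init__(self, data: pd.DataFrame):
        if data.empty:
            raise ValidationError("abundance table is empty")
        values = data.to_numpy(dtype=float, copy=True)
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite abundance at feature {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance {values[r, c]} at feature "
                f"{data.index[r]!r}, sample {data.columns[c]!r}"
            )
        _check_unique(data.index, "feature id")
        _check_unique(data.columns, "sample id")
        sums = values.sum(axis=0)
        bad = np.where(sums > 1 + COLUMN_SUM_TOL)[0]
        if bad.size:
            raise ValidationError(
                f"sample {data.columns[bad[0]]!r} column sum {sums[bad[0]]:.6g} exceeds 1"
            )
        self._data = pd.DataFrame(values, index=[str(i) for i in data.index],
                                  columns=[str(c) for c in data.columns])

    # -- accessors -----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return self._data.copy()

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self._data[sample_id].to_numpy()

    def feature_vector(self, feature_id: str) -> np.ndarray:
        return self._data.loc[feature_id].to_numpy()

    def select_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        return AbundanceTable(self._data[list(sample_ids)])

    def select_features(self, feature_ids: Iterable[str]) -> "AbundanceTable":
        return AbundanceTable(self._data.loc[list(feature_ids)])

    def renormalize(self) -> "AbundanceTable":
        """Divide each column by its sum (explicit, never automatic)."""
        sums = self._data.sum(axis=0)
        if (sums <= 0).any():
            bad = sums.index[sums <= 0][0]
            raise ValidationError(f"cannot renormalize sample {bad!r}: column sum is 0")
        return AbundanceTable(self._data / sums)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AbundanceTable)
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"AbundanceTable({len(self.feature_ids)} features x {len(self.sample_ids)} samples)"


class SampleMetadata:
    """Per-sample study design records.

    Required fields per sample: subject id, body site, collection day (integer
    days since study start), technical-replicate group (shared by repeat
    sequencings of one specimen) and a visit number.  Technical replicates
    must agree on subject, site and day.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        if len(frame) == 0:
            raise ValidationError("no samples in metadata")
        df = frame.copy()
        for col in ("sample_id", "subject_id", "body_site", "replicate_group"):
            df[col] = df[col].astype(str)
        df["collection_day"] = pd.to_numeric(df["collection_day"], errors="raise").astype(int)
        _check_unique(df["sample_id"], "sample id")
        if (df["collection_day"] < 0).any():
            bad = df.loc[df["collection_day"] < 0, "sample_id"].iloc[0]
            raise ValidationError(f"negative collection_day for sample {bad!r}")
        for group, sub in df.groupby("replicate_group"):
            for col in ("subject_id", "body_site", "collection_day"):
                if sub[col].nunique() > 1:
                    raise ValidationError(
                        f"replicate group {group!r} spans multiple values of {col}: "
                        f"{sorted(sub[col].unique().astype(str))}"
                    )
        if "visit_number" in df.columns:
            df["visit_number"] = pd.to_numeric(df["visit_number"], errors="raise").astype(int)
        else:
            # rank of collection day within (subject, site); replicates share a visit
            df["visit_number"] = (
                df.groupby(["subject_id", "body_site"])["collection_day"]
                .rank(method="dense")
                .astype(int)
            )
        self._frame = df.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self._frame["sample_id"])

    @property
    def body_sites(self) -> list[str]:
        return sorted(self._frame["body_site"].unique())

    def samples_at(self, site: str) -> list[str]:
        f = self._frame
        return list(f.loc[f["body_site"] == site, "sample_id"])

    def site_of(self) -> dict[str, str]:
        return dict(zip(self._frame["sample_id"], self._frame["body_site"]))

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        ids = set(sample_ids)
        return SampleMetadata(self._frame[self._frame["sample_id"].isin(ids)])

    def replicate_pairs(self) -> list[tuple[str, str]]:
        """All unordered pairs of samples sharing a replicate group."""
        pairs = []
        for _, sub in self._frame.groupby("replicate_group"):
            ids = list(sub["sample_id"])
            pairs.extend((a, b) for i, a in enumerate(ids) for b in ids[i + 1:])
        return pairs

    def __len__(self) -> int:
        return len(self._frame)

    def __repr__(self) -> str:
        f = self._frame
        return (
            f"SampleMetadata({len(f)} samples, {f['subject_id'].nunique()} subjects, "
            f"{f['body_site'].nunique()} sites)"
        )


@dataclass(frozen=True)
class StrainDistanceMatrix:
    """Square symmetric matrix of phylogenetic distances (substitutions/site)
    between dominant strain haplotypes, with a body-site label per sample."""

    sample_ids: tuple[str, ...]
    site_labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if values.shape != (n, n):
            raise ValidationError(f"distance matrix shape {values.shape} != ({n}, {n})")
        if len(self.site_labels) != n:
            raise ValidationError("one site label required per sample")
        _check_unique(self.sample_ids, "sample id")
        if not np.isfinite(values).all():
            raise ValidationError("non-finite distance")
        if (values < 0).any():
            raise ValidationError("negative distance")
        if np.abs(np.diag(values)).max(initial=0.0) > SYMMETRY_TOL:
            raise ValidationError("nonzero diagonal")
        asym = np.abs(values - values.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(np.abs(values - values.T)), values.shape)
            raise ValidationError(
                f"matrix asymmetric at ({self.sample_ids[i]!r}, {self.sample_ids[j]!r}): "
                f"|M[i,j]-M[j,i]| = {asym:.3g}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "site_labels", tuple(str(s) for s in self.site_labels))

    @property
    def sites(self) -> list[str]:
        return sorted(set(self.site_labels))

    def indices_in_site(self, site: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.site_labels) if s == site], dtype=int)

    def relabel(self, site_labels: Sequence[str]) -> "StrainDistanceMatrix":
        return StrainDistanceMatrix(self.sample_ids, tuple(site_labels), self.values)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, encoding="utf-8")


def read_abundance_table(path) -> AbundanceTable:
    """Read a feature-by-sample TSV (header row = sample ids, first column =
    feature ids) into a validated :class:`AbundanceTable`, preserving order."""
    df = _read_tsv(path)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric abundance value ({exc})") from exc
    return AbundanceTable(df)


def write_abundance_table(table: AbundanceTable, path) -> None:
    frame = table.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", encoding="utf-8")


def read_sample_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")
    if len(df) == 0:
        raise ValidationError(f"{path}: no samples")
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_distance_matrix(path, site_map: Mapping[str, str]) -> StrainDistanceMatrix:
    """Read a labeled square distance TSV; row and column labels must be the
    same set, and every sample must appear in ``site_map``."""
    df = _read_tsv(path).astype(float)
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if set(rows) != set(cols):
        raise ValidationError(f"{path}: row and column labels differ")
    df = df.loc[rows, rows]  # align columns to row order
    missing = [s for s in rows if s not in site_map]
    if missing:
        raise ValidationError(f"{path}: samples missing from site map: {missing}")
    sites = tuple(site_map[s] for s in rows)
    return StrainDistanceMatrix(tuple(rows), sites, df.to_numpy())


def write_distance_matrix(dm: StrainDistanceMatrix, path) -> None:
    frame = pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.sample_ids)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t", encoding="utf-8")


def read_annotation_table(path) -> dict[str, set[str]]:
    """Read a long-format pathway->genus annotation TSV (columns
    ``pathway``, ``genus``; one row per pair)."""
    df = pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")
    for col in ("pathway", "genus"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    out: dict[str, set[str]] = {}
    for p, g in zip(df["pathway"].astype(str), df["genus"].astype(str)):
        out.setdefault(p, set()).add(g)
    return out


def write_annotation_table(annotations: Mapping[str, Iterable[str]], path) -> None:
    rows = [(p, g) for p in sorted(annotations) for g in sorted(annotations[p])]
    pd.DataFrame(rows, columns=["pathway", "genus"]).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def read_fasta_alignment(path) -> dict[str, str]:
    """Read an aligned FASTA into an ordered {id: sequence} mapping.

    All sequences must have equal length (it is an alignment); ids must be
    unique.  Uses Bio.SeqIO for parsing.
    """
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValidationError(f"{path}: no sequences")
    lengths = {len(s) for s in records.values()}
    if len(lengths) > 1:
        raise ValidationError(f"{path}: unequal sequence lengths {sorted(lengths)}")
    return records
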
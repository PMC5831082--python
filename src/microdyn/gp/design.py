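"""Sampling design: who was sampled, when, and from which specimen."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SamplingDesign", "MONTHS_PER_DAY"]

#: days are the at-rest time unit; the GP works in months
MONTHS_PER_DAY = 12.0 / 365.25


@dataclass(frozen=True, eq=False)
class SamplingDesign:
    """Per-sample (subject, time, specimen) index used by every kernel.

    ``times_months`` is real-valued time in months; ``specimens`` identifies
    the physical specimen, shared by technical replicates.  Replicates of one
    specimen must agree on subject and time.
    """

    sample_ids: tuple[str, ...]
    subjects: tuple[str, ...]
    times_months: np.ndarray = field(repr=False)
    specimens: tuple[str, ...]

    def __post_init__(self):
        times = np.asarray(self.times_months, dtype=float)
        n = len(self.sample_ids)
        if not (len(self.subjects) == len(self.specimens) == times.size == n):
            raise ValueError("sample_ids, subjects, times and specimens must align")
        if n == 0:
            raise ValueError("empty design")
        if not np.isfinite(times).all() or (times < 0).any():
            raise ValueError("times must be finite and >= 0")
        by_specimen: dict[str, tuple[str, float]] = {}
        for subj, t, spec in zip(self.subjects, times, self.specimens):
            key = (subj, float(t))
            if spec in by_specimen and by_specimen[spec] != key:
                raise ValueError(
                    f"specimen {spec!r} attached to conflicting (subject, time): "
                    f"{by_specimen[spec]} vs {key}"
                )
            by_specimen[spec] = key
        object.__setattr__(self, "times_months", times)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SamplingDesign)
            and self.sample_ids == other.sample_ids
            and self.subjects == other.subjects
            and self.specimens == other.specimens
            and np.array_equal(self.times_months, other.times_months)
        )

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_subjects(self) -> int:
        return len(set(self.subjects))

    def replicate_pairs(self) -> list[tuple[int, int]]:
        """Index pairs of technical replicates (same specimen)."""
        groups: dict[str, list[int]] = {}
        for i, spec in enumerate(self.specimens):
            groups.setdefault(spec, []).append(i)
        return [
            (a, b)
            for idx in groups.values()
            for k, a in enumerate(idx)
            for b in idx[k + 1:]
        ]

    def without_replicates(self) -> "SamplingDesign":
        """Keep only the first sample of each specimen (drops the replicate
        information that separates biological from technical noise)."""
        seen: set[str] = set()
        keep = []
        for i, spec in enumerate(self.specimens):
            if spec not in seen:
                seen.add(spec)
                keep.append(i)
        return self.subset(keep)

    def subset(self, indices) -> "SamplingDesign":
        idx = list(indices)
        return SamplingDesign(
            tuple(self.sample_ids[i] for i in idx),
            tuple(self.subjects[i] for i in idx),
            self.times_months[idx],
            tuple(self.specimens[i] for i in idx),
        )

    @classmethod
    def from_metadata(cls, meta) -> "SamplingDesign":
        """Build a design from :class:`~microdyn.io_profiles.SampleMetadata`,
        converting collection days to months."""
        frame = meta.frame
        return cls(
            tuple(frame["sample_id"]),
            tuple(frame["subject_id"]),
            frame["collection_day"].to_numpy(dtype=float) * MONTHS_PER_DAY,
            tuple(frame["replicate_group"]),
        )
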
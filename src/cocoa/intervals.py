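"""Genomic interval data model and overlap/merge arithmetic.

Coordinates are 0-based half-open everywhere (BED convention). Strand is
ignored throughout. Chromosome names are matched by exact string equality;
any "chr"-prefix normalization happens at I/O time, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "RegionSetDatabase",
    "find_overlaps",
    "merge_intervals",
    "intervals_to_arrays",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a nonempty string")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class RegionSet:
    """A named, ordered collection of genomic intervals.

    Regions may overlap each other; no implicit merging is performed.
    ``metadata`` carries free-form annotations (source, factor, cell type).
    """

    name: str
    regions: list[GenomicInterval]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.regions)


@dataclass
class RegionSetDatabase:
    """An ordered collection of region sets with unique names."""

    sets: list[RegionSet]
    genome_label: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[RegionSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> RegionSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def intervals_to_arrays(
    regions: Iterable[GenomicInterval],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split intervals into (chroms, starts, ends) numpy arrays."""
    regions = list(regions)
    chroms = np.array([r.chrom for r in regions], dtype=object)
    starts = np.array([r.start for r in regions], dtype=np.int64)
    ends = np.array([r.end for r in regions], dtype=np.int64)
    return chroms, starts, ends


def find_overlaps(
    query: Iterable[GenomicInterval],
    subject: Iterable[GenomicInterval],
) -> list[tuple[int, int, int]]:
    """All overlapping (query_index, subject_index, overlap_length) pairs.

    Two half-open intervals on the same chromosome overlap iff
    ``max(starts) < min(ends)``; the overlap length is
    ``min(ends) - max(starts)``. Abutting intervals do not overlap.
    Results are sorted by query index, then subject index.
    """
    query = list(query)
    subject = list(subject)
    if not query or not subject:
        return []
    qc, qs, qe = intervals_to_arrays(query)
    sc, ss, se = intervals_to_arrays(subject)
    qi, si = overlap_pairs_arrays(qc, qs, qe, sc, ss, se)
    lengths = np.minimum(qe[qi], se[si]) - np.maximum(qs[qi], ss[si])
    return list(zip(qi.tolist(), si.tolist(), lengths.tolist()))


def overlap_pairs_arrays(
    qc: np.ndarray,
    qs: np.ndarray,
    qe: np.ndarray,
    sc: np.ndarray,
    ss: np.ndarray,
    se: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized overlap-pair search over coordinate arrays.

    Returns (query_indices, subject_indices) sorted by query then subject.
    Searches chromosome by chromosome with a sorted sweep over subject
    starts; candidate subjects are those starting before the query end,
    then filtered by ``subject_end > query_start``.
    """
    out_q: list[np.ndarray] = []
    out_s: list[np.ndarray] = []
    for chrom in np.unique(sc):
        s_idx = np.flatnonzero(sc == chrom)
        q_idx = np.flatnonzero(qc == chrom)
        if s_idx.size == 0 or q_idx.size == 0:
            continue
        order = np.argsort(ss[s_idx], kind="stable")
        s_idx = s_idx[order]
        s_starts = ss[s_idx]
        s_ends = se[s_idx]
        # subjects with start < query end are overlap candidates
        hi = np.searchsorted(s_starts, qe[q_idx], side="left")
        for qi_, hi_ in zip(q_idx, hi):
            if hi_ == 0:
                continue
            cand = s_idx[:hi_]
            keep = s_ends[:hi_] > qs[qi_]
            if keep.any():
                matched = cand[keep]
                out_q.append(np.full(matched.size, qi_, dtype=np.int64))
                out_s.append(matched)
    if not out_q:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy()
    qi = np.concatenate(out_q)
    si = np.concatenate(out_s)
    order = np.lexsort((si, qi))
    return qi[order], si[order]


def merge_intervals(
    regions: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Union of intervals, merging any that overlap.

    Output is sorted by (chrom, start). Abutting intervals (end == start)
    are *not* merged: half-open adjacency is not overlap, so the covered
    base count is preserved either way and adjacency stays visible.
    Idempotent.
    """
    regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    merged: list[GenomicInterval] = []
    for r in regions:
        if merged and merged[-1].chrom == r.chrom and r.start < merged[-1].end:
            prev = merged[-1]
            if r.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, r.end)
        else:
            merged.append(r)
    return merged
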
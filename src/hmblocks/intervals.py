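"""Genomic intervals and labeled region sets.

All coordinates are 0-based, half-open (BED convention). A :class:`RegionSet`
is the currency passed between pipeline stages: a labeled, sorted collection
of intervals, each optionally carrying metadata such as the parent
hypomethylated-block id, which side of the block it flanks, and the genomic
position of the block edge it is anchored to.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        """Whether a point position falls inside the half-open interval."""
        return self.start <= pos < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class RegionSet:
    """A labeled, sorted list of intervals with aligned per-interval metadata.

    Parameters
    ----------
    intervals:
        Any iterable of :class:`GenomicInterval`.
    label:
        Class label, e.g. ``boundary``, ``inside``, ``outside``, ``promoter``,
        ``block``, ``tad``, ``ctcf``, ``cpg`` or ``custom``.
    meta:
        Optional per-interval dicts (parent block id, side, anchor...). Kept
        aligned with the sorted interval order.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        label: str = "custom",
        meta: Sequence[Mapping] | None = None,
    ) -> None:
        ivs = list(intervals)
        if meta is None:
            metas: list[dict] = [{} for _ in ivs]
        else:
            metas = [dict(m) for m in meta]
            if len(metas) != len(ivs):
                raise ValueError("meta length does not match interval count")
        order = sorted(range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start, ivs[i].end))
        self.intervals: list[GenomicInterval] = [ivs[i] for i in order]
        self.meta: list[dict] = [metas[i] for i in order]
        self.label = label
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals and self.label == other.label

    def __repr__(self) -> str:
        return f"RegionSet(label={self.label!r}, n={len(self)})"

    # -- queries -------------------------------------------------------------
    def _build_index(self):
        if self._index is not None:
            return self._index
        index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            # running max of ends allows pruning the left scan for nested sets
            maxend = np.maximum.accumulate(ends)
            index[chrom] = (starts, ends, maxend)
        self._index = index
        return index

    def overlapping(self, query: GenomicInterval) -> list[int]:
        """Indices (within the per-chromosome order) of intervals overlapping
        ``query``; returned as indices into this set's global sorted order."""
        index = self._build_index()
        if query.chrom not in index:
            return []
        starts, ends, _ = index[query.chrom]
        # global positions of this chromosome's run in the sorted list
        offset = bisect.bisect_left([iv.chrom for iv in self.intervals], query.chrom)
        hi = int(np.searchsorted(starts, query.end, side="left"))
        hits = [
            offset + i
            for i in range(hi)
            if ends[i] > query.start
        ]
        return hits

    def any_overlap(self, query: GenomicInterval) -> bool:
        index = self._build_index()
        if query.chrom not in index:
            return False
        starts, ends, maxend = index[query.chrom]
        hi = int(np.searchsorted(starts, query.end, side="left"))
        if hi == 0:
            return False
        return bool(np.any(ends[:hi] > query.start))

    def count_overlapping(self, other: "RegionSet") -> int:
        """Number of intervals in this set overlapping at least one in other."""
        return sum(1 for iv in self.intervals if other.any_overlap(iv))

    def is_nonoverlapping(self) -> bool:
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                return False
        return True

    def first_overlapping_pair(self) -> tuple[GenomicInterval, GenomicInterval] | None:
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                return a, b
        return None

    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def subset(self, indices: Sequence[int], label: str | None = None) -> "RegionSet":
        return RegionSet(
            [self.intervals[i] for i in indices],
            label=label or self.label,
            meta=[self.meta[i] for i in indices],
        )

    # -- BED I/O -------------------------------------------------------------
    def to_bed(self, path: str | Path) -> None:
        """Write as 6-column BED (name column carries ``key=value`` metadata)."""
        path = Path(path)
        with path.open("w") as fh:
            for iv, meta in zip(self.intervals, self.meta):
                name = ";".join(f"{k}={v}" for k, v in sorted(meta.items())) or "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
                )

    @classmethod
    def from_bed(cls, path: str | Path, label: str = "custom") -> "RegionSet":
        intervals: list[GenomicInterval] = []
        metas: list[dict] = []
        with Path(path).open() as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed BED line in {path}: {line!r}")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                strand = parts[5] if len(parts) >= 6 and parts[5] in STRANDS else "."
                meta: dict = {}
                if len(parts) >= 4 and parts[3] not in (".", ""):
                    for token in parts[3].split(";"):
                        if "=" in token:
                            k, v = token.split("=", 1)
                            meta[k] = _coerce(v)
                intervals.append(GenomicInterval(chrom, start, end, strand))
                metas.append(meta)
        return cls(intervals, label=label, meta=metas)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column ``chrom<TAB>size`` file."""
    sizes: dict[str, int] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")
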
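"""Boundary-region construction and GC-matched control sampling.

A hypomethylated block (HMB) contributes two boundary regions: a window of
``flank_outside`` bases outside each block edge plus ``flank_inside`` bases
inside it (defaults 5 kb + 1 kb = 6 kb). Control region classes — random
windows *inside* blocks, *outside* blocks, and gene *promoters* — are sampled
to the same fixed length, kept disjoint from the boundaries and from each
other, and matched to the boundary GC-content distribution so that sequence
composition does not drive the downstream classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .genome import Genome
from .intervals import GenomicInterval, RegionSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundarySpec:
    """Geometry of a block-boundary region.

    ``flank_outside`` bases outside the block edge plus ``flank_inside``
    bases inside it; their sum is the fixed region length used everywhere
    downstream.
    """

    flank_outside: int = 5000
    flank_inside: int = 1000

    def __post_init__(self) -> None:
        if self.flank_outside <= 0 or self.flank_inside <= 0:
            raise ValueError("flank lengths must be positive")

    @property
    def region_length(self) -> int:
        return self.flank_outside + self.flank_inside


class PlacementError(RuntimeError):
    """Raised when non-overlapping placement of regions fails."""

    def __init__(self, message: str, achieved: int = 0):
        super().__init__(message)
        self.achieved = achieved


def derive_boundaries(
    blocks: RegionSet,
    spec: BoundarySpec = BoundarySpec(),
    chrom_sizes: Mapping[str, int] | None = None,
) -> RegionSet:
    """Two boundary regions per block; regions clipped by chromosome edges
    are dropped (not truncated) so every region has the same length.

    Each region's metadata records the parent block index, the side
    (``left``/``right``) and the ``anchor`` — the genomic position of the
    block edge, used to orient metaprofiles and positional profiles.
    """
    if not blocks.is_nonoverlapping():
        pair = blocks.first_overlapping_pair()
        raise ValueError(f"input blocks overlap: {pair[0]} / {pair[1]}")
    intervals: list[GenomicInterval] = []
    meta: list[dict] = []
    n_dropped = 0
    short_blocks = 0
    for bid, block in enumerate(blocks):
        size = None if chrom_sizes is None else chrom_sizes.get(block.chrom)
        if block.length < 2 * spec.flank_inside:
            short_blocks += 1
        for side in ("left", "right"):
            if side == "left":
                anchor = block.start
                start = block.start - spec.flank_outside
                end = block.start + spec.flank_inside
            else:
                anchor = block.end
                start = block.end - spec.flank_inside
                end = block.end + spec.flank_outside
            if start < 0 or (size is not None and end > size):
                n_dropped += 1
                continue
            intervals.append(GenomicInterval(block.chrom, start, end))
            meta.append({"block": bid, "side": side, "anchor": anchor})
    if n_dropped:
        log.info("dropped %d boundary regions clipped by chromosome edges", n_dropped)
    if short_blocks:
        log.warning(
            "%d blocks shorter than %d b: their two inside flanks overlap",
            short_blocks,
            2 * spec.flank_inside,
        )
    return RegionSet(intervals, label="boundary", meta=meta)


def _eligible_segments(
    blocks: RegionSet,
    boundaries: RegionSet,
    kind: str,
    chrom_sizes: Mapping[str, int],
    length: int,
) -> list[tuple[str, int, int]]:
    """Maximal segments of the eligible space (inside or outside blocks,
    minus all boundary regions) able to host at least one region."""
    base: list[tuple[str, int, int]] = []
    if kind == "inside":
        for block in blocks:
            base.append((block.chrom, block.start, block.end))
    elif kind == "outside":
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for block in blocks:
            by_chrom.setdefault(block.chrom, []).append(block)
        for chrom, size in chrom_sizes.items():
            pos = 0
            for block in sorted(by_chrom.get(chrom, []), key=lambda b: b.start):
                if block.start > pos:
                    base.append((chrom, pos, block.start))
                pos = max(pos, block.end)
            if pos < size:
                base.append((chrom, pos, size))
    else:
        raise ValueError(f"unknown control kind {kind!r}")

    # subtract boundary regions
    segments: list[tuple[str, int, int]] = []
    for chrom, s, e in base:
        cuts = [
            (max(s, iv.start), min(e, iv.end))
            for iv in boundaries
            if iv.chrom == chrom and iv.start < e and iv.end > s
        ]
        pos = s
        for cs, ce in sorted(cuts):
            if cs > pos:
                segments.append((chrom, pos, cs))
            pos = max(pos, ce)
        if pos < e:
            segments.append((chrom, pos, e))
    return [(c, s, e) for c, s, e in segments if e - s >= length]


def sample_controls(
    blocks: RegionSet,
    boundaries: RegionSet,
    kind: str,
    n: int,
    length: int,
    rng: np.random.Generator,
    chrom_sizes: Mapping[str, int] | None = None,
    allow_shortfall: bool = False,
) -> RegionSet:
    """Rejection-sample ``n`` non-overlapping fixed-length control regions.

    ``kind='inside'`` draws fully within blocks, ``kind='outside'`` fully
    between them; both exclude all boundary regions. The attempt budget is
    10×n; exhausting it raises :class:`PlacementError` reporting the achieved
    count unless ``allow_shortfall`` is set, in which case the regions placed
    so far are returned.
    """
    if chrom_sizes is None:
        sizes: dict[str, int] = {}
        for iv in list(blocks) + list(boundaries):
            sizes[iv.chrom] = max(sizes.get(iv.chrom, 0), iv.end)
        chrom_sizes = sizes
    segments = _eligible_segments(blocks, boundaries, kind, chrom_sizes, length)
    if not segments:
        raise PlacementError(
            f"no eligible space for {kind} controls of length {length}", achieved=0
        )
    # feasible start mass per segment for uniform start sampling
    weights = np.array([e - s - length + 1 for _, s, e in segments], dtype=float)
    weights /= weights.sum()
    placed: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    attempts = 0
    budget = 10 * n
    while len(placed) < n and attempts < budget:
        attempts += 1
        si = rng.choice(len(segments), p=weights)
        chrom, s, e = segments[si]
        start = int(rng.integers(s, e - length + 1))
        end = start + length
        clash = any(start < oe and os_ < end for os_, oe in occupied.get(chrom, []))
        if clash:
            continue
        occupied.setdefault(chrom, []).append((start, end))
        placed.append(GenomicInterval(chrom, start, end))
    if len(placed) < n and not allow_shortfall:
        raise PlacementError(
            f"placed only {len(placed)}/{n} {kind} controls within {budget} attempts",
            achieved=len(placed),
        )
    if len(placed) < n:
        log.warning("control shortfall: %d/%d %s regions placed", len(placed), n, kind)
    return RegionSet(placed, label=kind)


def derive_promoters(tss: RegionSet, up: int = 5000, down: int = 1000) -> RegionSet:
    """Strand-aware promoter windows: ``up`` bases upstream through ``down``
    bases downstream of each TSS; minus-strand promoters are mirrored.
    Overlapping promoters are deduplicated keeping the first in sorted order.
    """
    intervals: list[GenomicInterval] = []
    for iv in tss:
        if iv.strand not in ("+", "-"):
            raise ValueError(f"TSS without strand: {iv}")
        pos = iv.start
        if iv.strand == "+":
            start, end = pos - up, pos + down
        else:
            start, end = pos - down, pos + up
        if start < 0:
            continue
        intervals.append(GenomicInterval(iv.chrom, start, end, iv.strand))
    ordered = sorted(intervals, key=lambda x: (x.chrom, x.start, x.end))
    kept: list[GenomicInterval] = []
    for iv in ordered:
        if kept and kept[-1].overlaps(iv):
            continue
        kept.append(iv)
    return RegionSet(kept, label="promoter")


def gc_match(
    cases: RegionSet,
    candidates: RegionSet,
    genome: Genome,
    rng: np.random.Generator,
    bin_width: float = 0.02,
) -> tuple[RegionSet, dict[int, int]]:
    """Subsample ``candidates`` so their GC histogram matches the cases'.

    GC fractions are binned at ``bin_width``; within each occupied bin the
    needed number of candidates is drawn at random. Returns the matched set
    and a per-bin shortfall report (bin index → missing count); shortfall is
    reported, never fatal.
    """

    def bins(rs: RegionSet) -> np.ndarray:
        gc = np.array([genome.gc_fraction(iv.chrom, iv.start, iv.end) for iv in rs])
        return np.minimum((gc / bin_width).astype(int), int(1 / bin_width) - 1)

    case_bins = bins(cases)
    cand_bins = bins(candidates)
    selected: list[int] = []
    shortfall: dict[int, int] = {}
    for b in np.unique(case_bins):
        need = int((case_bins == b).sum())
        pool = np.flatnonzero(cand_bins == b)
        take = min(need, len(pool))
        if take:
            chosen = rng.choice(pool, size=take, replace=False)
            selected.extend(int(i) for i in chosen)
        if take < need:
            shortfall[int(b)] = need - take
    if shortfall:
        log.warning(
            "GC matching shortfall: %d regions missing across %d bins",
            sum(shortfall.values()),
            len(shortfall),
        )
    return candidates.subset(sorted(selected)), shortfall


def exclude_tss_overlaps(regions: RegionSet, tss: RegionSet) -> RegionSet:
    """Drop regions containing at least one TSS position (half-open: a TSS
    exactly at region end is outside). The removal count is logged."""
    tss_by_chrom: dict[str, list[int]] = {}
    for iv in tss:
        tss_by_chrom.setdefault(iv.chrom, []).append(iv.start)
    tss_arrays = {c: np.sort(np.array(p, dtype=np.int64)) for c, p in tss_by_chrom.items()}
    keep: list[int] = []
    removed = 0
    for i, iv in enumerate(regions.intervals):
        positions = tss_arrays.get(iv.chrom)
        if positions is None:
            keep.append(i)
            continue
        lo = np.searchsorted(positions, iv.start, side="left")
        hi = np.searchsorted(positions, iv.end, side="left")
        if hi > lo:
            removed += 1
        else:
            keep.append(i)
    log.info("excluded %d/%d regions overlapping a TSS", removed, len(regions))
    return regions.subset(keep)


def assert_disjoint(*sets: RegionSet) -> None:
    """Raise if any two region classes overlap (pairwise check)."""
    for i, a in enumerate(sets):
        for b in sets[i + 1 :]:
            for iv in a:
                if b.any_overlap(iv):
                    raise ValueError(
                        f"region classes {a.label!r} and {b.label!r} overlap at {iv}"
                    )
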
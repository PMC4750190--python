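"""Hi-C intra-block interaction strength and TAD-boundary proximity.

Contact matrices are dense, symmetric, per-chromosome, at 40-kb bins
(normalized upstream; taken as given). A 40-kb bin belongs to a block only
when it lies entirely within it, so blocks shorter than one bin are
excluded. A block's interaction strength is the sum of contacts over its
distinct within-block bin pairs (diagonal excluded) divided by its bin
count. Both the strength statistic and the TAD-boundary distance statistic
are compared against length-matched random non-overlapping regions by the
two-sided rank-sum test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, RegionSet
from .stats import rank_sum_test


@dataclass
class HiCMatrix:
    chrom: str
    matrix: np.ndarray
    bin_width: int = 40000

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("Hi-C matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-6):
            raise ValueError("Hi-C matrix must be symmetric")
        if (self.matrix < 0).any():
            raise ValueError("Hi-C matrix must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def write(self, prefix: str | Path) -> None:
        """Dense whitespace matrix plus a JSON sidecar (chrom, bin_width)."""
        prefix = Path(prefix)
        np.savetxt(str(prefix) + ".txt", self.matrix, fmt="%.6g")
        Path(str(prefix) + ".json").write_text(
            json.dumps({"chrom": self.chrom, "bin_width": self.bin_width})
        )

    @classmethod
    def read(cls, prefix: str | Path) -> "HiCMatrix":
        prefix = Path(prefix)
        meta = json.loads(Path(str(prefix) + ".json").read_text())
        matrix = np.loadtxt(str(prefix) + ".txt")
        return cls(chrom=meta["chrom"], matrix=matrix, bin_width=meta["bin_width"])


@dataclass
class InteractionSummary:
    block_id: int
    n_bins: int
    strength: float


def map_blocks_to_bins(
    blocks: RegionSet, matrix: HiCMatrix
) -> tuple[dict[int, list[int]], int]:
    """Bin indices fully contained in each block (same chromosome only);
    blocks with zero fully contained bins are excluded and counted."""
    bw = matrix.bin_width
    mapping: dict[int, list[int]] = {}
    excluded = 0
    for bid, block in enumerate(blocks):
        if block.chrom != matrix.chrom:
            continue
        first = -(-block.start // bw)  # ceil division: first bin start >= block start
        bins = []
        b = first
        while (b + 1) * bw <= block.end and b < matrix.n_bins:
            bins.append(b)
            b += 1
        if bins:
            mapping[bid] = bins
        else:
            excluded += 1
    return mapping, excluded


def interaction_strength(
    block_id: int, bins: Sequence[int], matrix: HiCMatrix
) -> InteractionSummary | None:
    """Sum of contacts over distinct within-block bin pairs divided by the
    bin count; blocks with fewer than 2 bins are excluded (None)."""
    if len(bins) < 2:
        return None
    sub = matrix.matrix[np.ix_(bins, bins)]
    total = float(np.triu(sub, k=1).sum())
    return InteractionSummary(block_id=block_id, n_bins=len(bins), strength=total / len(bins))


def block_strengths(
    blocks: RegionSet, matrices: Mapping[str, HiCMatrix]
) -> list[InteractionSummary]:
    out: list[InteractionSummary] = []
    for chrom, matrix in sorted(matrices.items()):
        mapping, _ = map_blocks_to_bins(blocks, matrix)
        for bid, bins in sorted(mapping.items()):
            summary = interaction_strength(bid, bins, matrix)
            if summary is not None:
                out.append(summary)
    return out


def _random_length_matched(
    blocks: RegionSet,
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
    max_attempts_factor: int = 10,
) -> RegionSet:
    """Non-overlapping random regions with the same lengths as the blocks."""
    lengths = sorted((iv.length for iv in blocks), reverse=True)  # large first
    chroms = sorted(chrom_sizes)
    placed: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    budget = max_attempts_factor * len(lengths)
    attempts = 0
    for length in lengths:
        ok = False
        while attempts < budget:
            attempts += 1
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            size = chrom_sizes[chrom]
            if size <= length:
                continue
            start = int(rng.integers(0, size - length))
            end = start + length
            if any(start < oe and os_ < end for os_, oe in occupied.get(chrom, [])):
                continue
            occupied.setdefault(chrom, []).append((start, end))
            placed.append(GenomicInterval(chrom, start, end))
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"random length-matched placement failed after {attempts} attempts "
                f"({len(placed)}/{len(lengths)} placed)"
            )
    return RegionSet(placed, label="random")


def strength_vs_random(
    blocks: RegionSet,
    matrices: Mapping[str, HiCMatrix],
    rng: np.random.Generator,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict:
    """Per-block interaction strengths against a length-matched random
    control, compared by the two-sided rank-sum test."""
    if chrom_sizes is None:
        chrom_sizes = {c: m.n_bins * m.bin_width for c, m in matrices.items()}
    real = [s.strength for s in block_strengths(blocks, matrices)]
    control_set = _random_length_matched(blocks, chrom_sizes, rng)
    control = [s.strength for s in block_strengths(control_set, matrices)]
    out = {
        "n_blocks": len(real),
        "n_random": len(control),
        "mean_blocks": float(np.mean(real)) if real else float("nan"),
        "mean_random": float(np.mean(control)) if control else float("nan"),
    }
    if len(real) >= 2 and len(control) >= 2:
        u, p = rank_sum_test(real, control)
        out.update(u=u, p_value=p)
    else:
        out.update(u=float("nan"), p_value=float("nan"), skipped=True)
    return out


def boundary_positions(blocks: RegionSet) -> dict[str, np.ndarray]:
    """Block starts and ends per chromosome, sorted (both edges count)."""
    pos: dict[str, list[int]] = {}
    for iv in blocks:
        pos.setdefault(iv.chrom, []).extend((iv.start, iv.end))
    return {c: np.sort(np.array(p, dtype=np.int64)) for c, p in pos.items()}


def min_distances(tads: RegionSet, blocks: RegionSet) -> np.ndarray:
    """For each TAD boundary (start and end of each TAD), the minimum
    distance to any block boundary on the same chromosome."""
    edges = boundary_positions(blocks)
    dists: list[int] = []
    for iv in tads:
        targets = edges.get(iv.chrom)
        if targets is None or len(targets) == 0:
            continue
        for p in (iv.start, iv.end):
            i = int(np.searchsorted(targets, p))
            best = min(
                abs(p - targets[j]) for j in (i - 1, i) if 0 <= j < len(targets)
            )
            dists.append(best)
    return np.array(dists, dtype=np.int64)


def tad_proximity(
    tads: RegionSet,
    blocks: RegionSet,
    rng: np.random.Generator,
    chrom_sizes: Mapping[str, int],
) -> dict:
    """Distances from TAD boundaries to the nearest block boundary versus
    the same statistic against length-matched random blocks."""
    if len(tads) == 0 or len(blocks) == 0:
        raise ValueError("both TAD and block sets must be nonempty")
    real = min_distances(tads, blocks)
    control_blocks = _random_length_matched(blocks, chrom_sizes, rng)
    control = min_distances(tads, control_blocks)
    u, p = rank_sum_test(real, control)
    return {
        "n_tad_boundaries": int(len(real)),
        "mean_real": float(real.mean()),
        "median_real": float(np.median(real)),
        "mean_control": float(control.mean()),
        "median_control": float(np.median(control)),
        "ratio_of_means": float(control.mean() / real.mean()) if real.mean() else float("inf"),
        "ratio_of_medians": (
            float(np.median(control) / np.median(real)) if np.median(real) else float("inf")
        ),
        "u": u,
        "p_value": p,
    }
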
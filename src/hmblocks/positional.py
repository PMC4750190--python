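"""Positional profiles of motif hits across fixed-length boundary regions.

Hits are assigned to 100-bp windows by the start coordinate of the match.
Right-side boundary regions are mirrored so that window 0 is always the
outermost (furthest outside the block) end and the block edge sits at a
fixed offset; "toward the block interior" is then one consistent direction
for both boundaries of a block. The positional-bias statistic is the
Z-score of the most extreme window count against the mean and population
standard deviation over all windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import RegionSet
from .motifs import MotifHit, region_id_of


@dataclass
class PositionalProfile:
    motif_id: str
    window_counts: np.ndarray  # mean hits per window per region
    total_hits: int
    n_regions: int
    window: int
    edge_window: int  # window index containing the block edge
    z: float = float("nan")
    extreme_window_index: int = -1
    extreme_offset: int = -1
    sd_zero: bool = False

    @property
    def n_windows(self) -> int:
        return len(self.window_counts)


def profile(
    hits: Iterable[MotifHit],
    regions: RegionSet,
    motif_id: str,
    window: int = 100,
    edge_offset: int = 5000,
) -> PositionalProfile:
    """Average per-window hit counts for one motif over equal-length regions.

    ``edge_offset`` is the distance from the outside end of a region to the
    block edge (the outside flank length); right-side regions (metadata
    ``side == 'right'``) are mirrored before window assignment.
    """
    lengths = {iv.length for iv in regions}
    if len(lengths) != 1:
        raise ValueError("regions must share one length")
    length = lengths.pop()
    if length % window != 0:
        raise ValueError(f"region length {length} not divisible by window {window}")
    n_windows = length // window
    sides = {
        region_id_of(regions.label, i): meta.get("side", "left")
        for i, meta in enumerate(regions.meta)
    }
    counts = np.zeros(n_windows)
    total = 0
    for h in hits:
        if h.motif_id != motif_id or h.region_id not in sides:
            continue
        offset = h.offset
        if sides[h.region_id] == "right":
            offset = length - 1 - offset
        counts[offset // window] += 1
        total += 1
    n_regions = max(len(regions), 1)
    prof = PositionalProfile(
        motif_id=motif_id,
        window_counts=counts / n_regions,
        total_hits=total,
        n_regions=len(regions),
        window=window,
        edge_window=edge_offset // window,
    )
    return z_score(prof)


def z_score(prof: PositionalProfile) -> PositionalProfile:
    """Fill in the extreme-window Z-score: |extreme - mean| / population sd
    over the windows. Ties for the extreme break toward the window nearest
    the block edge. sd = 0 is reported as z = 0 with a flag."""
    counts = prof.window_counts
    mean = counts.mean()
    sd = counts.std()  # population sd (divide by n)
    dev = np.abs(counts - mean)
    extreme_dev = dev.max()
    candidates = np.flatnonzero(np.isclose(dev, extreme_dev))
    idx = int(candidates[np.argmin(np.abs(candidates - prof.edge_window))])
    prof.extreme_window_index = idx
    prof.extreme_offset = idx * prof.window
    if sd == 0:
        prof.z = 0.0
        prof.sd_zero = True
    else:
        prof.z = float(extreme_dev / sd)
        prof.sd_zero = False
    return prof


def profile_table(profiles: Sequence[PositionalProfile]) -> pd.DataFrame:
    """One row per motif: window columns, z, extreme offset."""
    rows = []
    for p in profiles:
        row = {f"w{i:02d}": v for i, v in enumerate(p.window_counts)}
        row.update(
            motif=p.motif_id,
            z=p.z,
            extreme_window=p.extreme_window_index,
            extreme_offset=p.extreme_offset,
            total_hits=p.total_hits,
            sd_zero=p.sd_zero,
        )
        rows.append(row)
    df = pd.DataFrame(rows).set_index("motif")
    return df


def write_profiles(profiles: Sequence[PositionalProfile], path: str | Path) -> None:
    profile_table(profiles).to_csv(path, sep="\t")
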
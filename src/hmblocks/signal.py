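"""Binned ChIP signal: normalization, region summaries, boundary-aligned
metaprofiles and CTCF-stratified comparisons.

Tracks are fixed-width bins (20 bp as distributed by Roadmap). Treatment is
normalized against its input as ``log((t + eps) / (i + eps))`` (natural log,
eps = 0.5); missing bins (NaN) propagate. Metaprofiles average the
normalized signal as a function of distance to the block edge, with
right-side boundaries mirrored so negative offsets always point outside the
block.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .intervals import RegionSet
from .stats import rank_sum_test


@dataclass
class BinnedTrack:
    values: dict[str, np.ndarray]  # chrom -> per-bin values, NaN = missing
    bin_width: int = 20

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def same_grid(self, other: "BinnedTrack") -> bool:
        return self.bin_width == other.bin_width and {
            c: len(v) for c, v in self.values.items()
        } == {c: len(v) for c, v in other.values.items()}

    def to_bedgraph(self, path: str | Path) -> None:
        """4-column bedGraph-like file with fixed-width bins; missing bins
        written as ``nan`` so the grid round-trips exactly."""
        with Path(path).open("w") as fh:
            for chrom in sorted(self.values):
                vals = self.values[chrom]
                for i, v in enumerate(vals):
                    start = i * self.bin_width
                    fh.write(f"{chrom}\t{start}\t{start + self.bin_width}\t{v:.6g}\n")

    @classmethod
    def from_bedgraph(cls, path: str | Path, bin_width: int = 20) -> "BinnedTrack":
        df = pd.read_csv(
            path, sep="\t", names=["chrom", "start", "end", "value"], comment="#"
        )
        values: dict[str, np.ndarray] = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            n = int(grp["end"].max() // bin_width)
            arr = np.full(n, np.nan)
            idx = (grp["start"] // bin_width).to_numpy()
            arr[idx] = grp["value"].to_numpy()
            values[str(chrom)] = arr
        return cls(values, bin_width=bin_width)


def normalize(
    treatment: BinnedTrack, input_track: BinnedTrack, pseudocount: float = 0.5
) -> BinnedTrack:
    """Per-bin ``log((t + eps)/(i + eps))`` (natural log); NaN propagates."""
    if not treatment.same_grid(input_track):
        raise ValueError("treatment and input tracks are on different bin grids")
    out = {
        c: np.log((treatment.values[c] + pseudocount) / (input_track.values[c] + pseudocount))
        for c in treatment.values
    }
    return BinnedTrack(out, bin_width=treatment.bin_width)


def region_mean(track: BinnedTrack, regions: RegionSet) -> np.ndarray:
    """Mean track value over each region, weighting partial edge bins by
    their overlap fraction; missing bins are excluded from the mean. A
    region with no defined bins yields NaN."""
    bw = track.bin_width
    out = np.empty(len(regions))
    for i, iv in enumerate(regions):
        if iv.chrom not in track.values:
            raise ValueError(f"chromosome {iv.chrom} absent from track")
        vals = track.values[iv.chrom]
        if iv.end > len(vals) * bw:
            raise ValueError(f"region {iv} outside track extent")
        first = iv.start // bw
        last = (iv.end - 1) // bw
        idx = np.arange(first, last + 1)
        bin_starts = idx * bw
        weights = (
            np.minimum(bin_starts + bw, iv.end) - np.maximum(bin_starts, iv.start)
        ).astype(float)
        v = vals[idx]
        ok = ~np.isnan(v)
        wsum = weights[ok].sum()
        out[i] = np.dot(weights[ok], v[ok]) / wsum if wsum > 0 else np.nan
    return out


@dataclass
class MetaProfile:
    offsets: np.ndarray  # bin-center offsets, negative = outside the block
    mean_signal: np.ndarray
    n_regions: int
    bin_width: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean_signal": self.mean_signal})


def metaprofile(
    track: BinnedTrack, boundaries: RegionSet, span: int = 20000
) -> MetaProfile:
    """Mean signal by distance to the block edge over ±``span`` bases.

    Each boundary must carry ``anchor`` (block-edge position) and ``side``
    metadata; right-side anchors are mirrored so positive offsets point into
    the block. Offsets that fall outside a chromosome contribute nothing.
    """
    bw = track.bin_width
    n_off = 2 * (span // bw)
    sums = np.zeros(n_off)
    counts = np.zeros(n_off)
    ks = np.arange(n_off)
    offs = (ks - n_off // 2) * bw  # signed genomic offset of bin start
    for iv, meta in zip(boundaries.intervals, boundaries.meta):
        if "anchor" not in meta or "side" not in meta:
            raise ValueError("boundary regions need 'anchor' and 'side' metadata")
        anchor, side = int(meta["anchor"]), meta["side"]
        vals = track.values[iv.chrom]
        if side == "left":
            pos = anchor + offs
        else:
            pos = anchor - offs - bw
        b = pos // bw  # containing bin; anchors need not be bin-aligned
        valid = (b >= 0) & (b < len(vals))
        v = vals[b[valid]]
        ok = ~np.isnan(v)
        np.add.at(sums, ks[valid][ok], v[ok])
        np.add.at(counts, ks[valid][ok], 1)
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    offsets = (np.arange(n_off) - n_off // 2) * bw + bw / 2
    return MetaProfile(offsets=offsets, mean_signal=mean, n_regions=len(boundaries), bin_width=bw)


def compare_sets(
    track: BinnedTrack, set_a: RegionSet, set_b: RegionSet
) -> dict[str, float]:
    """Per-region means of the two sets compared by the two-sided rank-sum
    test (exact for small untied samples, normal approximation otherwise)."""
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValueError("need at least 2 regions per set")
    a = region_mean(track, set_a)
    b = region_mean(track, set_b)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    u, p = rank_sum_test(a, b)
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "u": u,
        "p_value": p,
    }


def ctcf_stratify(
    track: BinnedTrack | None, boundaries: RegionSet, ctcf: RegionSet
) -> dict:
    """CTCF overlap frequency of boundary regions and, when a track is
    given, the signal comparison between boundaries with and without a
    CTCF site."""
    has = np.array([ctcf.any_overlap(iv) for iv in boundaries], dtype=bool)
    out: dict = {
        "n_boundaries": len(boundaries),
        "n_with_ctcf": int(has.sum()),
        "freq_with": float(has.mean()) if len(boundaries) else 0.0,
        "comparison_skipped": False,
    }
    if len(ctcf) == 0 or track is None or has.sum() < 2 or (~has).sum() < 2:
        out["comparison_skipped"] = True
        return out
    means = region_mean(track, boundaries)
    with_ctcf = means[has & ~np.isnan(means)]
    without = means[(~has) & ~np.isnan(means)]
    u, p = rank_sum_test(with_ctcf, without)
    out.update(
        mean_with=float(with_ctcf.mean()),
        mean_without=float(without.mean()),
        u=u,
        p_value=p,
    )
    return out


def region_frequency(regions: RegionSet, sites: RegionSet) -> float:
    """Fraction of regions overlapped by at least one site."""
    if len(regions) == 0:
        return 0.0
    return sum(1 for iv in regions if sites.any_overlap(iv)) / len(regions)
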
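"""Synthetic bundle generator: every pipeline input, with planted structure.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale, so each stage can be tested against a known truth
record with no external download:

* i.i.d. uniform-GC background sequence on a few megabase chromosomes;
* non-overlapping blocks with lognormal lengths whose log-sd (1.609) keeps
  the heavy-tailed mean/median ratio of real hypomethylated blocks (~3.6);
* a PWM library in which a configurable fraction of motifs is planted into
  boundary regions at a higher rate than the genome-wide background, with
  planted positions peaked near the block edge;
* a promoter-like ChIP mark with a Poisson peak just outside each block
  edge over flat background, and a flat control mark;
* symmetric nonnegative Hi-C matrices with within-block bin pairs lifted by
  a configured boost;
* TAD intervals equal to blocks with Gaussian-jittered edges (or placed at
  random when the jitter is infinite, the null);
* CTCF sites over-placed on boundary regions, CpG islands on a fraction of
  block edges, TSS for a promoter control class, and a TF-interaction /
  chromatin-modification-enzyme map wired preferentially to planted motifs.

All randomness derives from one seed through named SeedSequence substreams
(genome, blocks, motifs, planting, cpg, ctcf, chip, hic, tads, genes, cme),
so the full bundle is reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .chromatin3d import HiCMatrix, map_blocks_to_bins, _random_length_matched
from .enrichment import InteractionMap
from .genome import Genome
from .intervals import GenomicInterval, RegionSet, write_chrom_sizes
from .motifs import PWM, read_meme, write_meme
from .regions import BoundarySpec, derive_boundaries, PlacementError

_STREAMS = (
    "genome",
    "blocks",
    "motifs",
    "planting",
    "cpg",
    "ctcf",
    "chip",
    "hic",
    "tads",
    "genes",
    "cme",
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic bundle. Defaults are the desk-scale
    conditions the recovery experiments run under: ~50 blocks on a ~3-Mb
    genome with a 30-motif library, half of it boundary-enriched."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_600_000
    n_blocks: int = 50
    block_length_log_mean: float = math.log(12_000)
    block_length_log_sd: float = 1.609
    min_block_length: int = 2_400
    max_block_length: int | None = None  # None -> chrom_length // 10
    n_motifs: int = 30
    motif_width_range: tuple[int, int] = (8, 12)
    boundary_enriched_fraction: float = 0.5
    boundary_planting_rate: float = 4.0
    background_planting_rate: float = 0.5
    boundary_offset_sd: float = 300.0
    gc_content: float = 0.5
    boundary_spec: BoundarySpec = field(default_factory=BoundarySpec)
    cpg_island_fraction: float = 0.3
    cpg_island_length: int = 1_000
    chip_peak_height: float = 20.0
    chip_background: float = 5.0
    chip_peak_sd: float = 600.0
    chip_peak_offset: float = -500.0  # peak center relative to edge, negative = outside
    chip_bin_width: int = 20
    hic_bin_width: int = 40_000
    hic_background_mean: float = 10.0
    hic_intra_boost: float = 15.0
    tad_jitter_sd: float = 5_000.0
    ctcf_boundary_prob: float = 0.3
    ctcf_background_prob: float = 0.1
    ctcf_site_length: int = 200
    n_genes: int = 40
    n_cme_genes: int = 60
    cme_prob_enriched: float = 0.6
    cme_prob_background: float = 0.2

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_blocks", "n_motifs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "boundary_enriched_fraction",
            "gc_content",
            "ctcf_boundary_prob",
            "ctcf_background_prob",
            "cpg_island_fraction",
            "cme_prob_enriched",
            "cme_prob_background",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        # equality of the two rates is the explicit exchangeable-null setup
        if self.boundary_planting_rate < self.background_planting_rate:
            raise ValueError(
                "boundary_planting_rate must be >= background_planting_rate"
            )

    @classmethod
    def null(cls, seed: int = 0, **kw) -> "SimConfig":
        """Exchangeable null: no boundary excess anywhere — equal planting
        rates, no Hi-C lift, TADs unrelated to blocks, no CTCF excess."""
        kw.setdefault("background_planting_rate", 0.5)
        kw.setdefault("boundary_planting_rate", kw["background_planting_rate"])
        kw.setdefault("hic_intra_boost", 0.0)
        kw.setdefault("tad_jitter_sd", math.inf)
        kw.setdefault("ctcf_boundary_prob", kw.get("ctcf_background_prob", 0.1))
        # edge-planted CpG islands would also distinguish boundaries
        kw.setdefault("cpg_island_fraction", 0.0)
        return cls(seed=seed, **kw)

    @classmethod
    def chromatin(cls, seed: int = 0, **kw) -> "SimConfig":
        """3D-structure study conditions: fewer, larger blocks on a 16-Mb
        genome so most blocks span several 40-kb Hi-C bins."""
        defaults = dict(
            seed=seed,
            n_chromosomes=2,
            chrom_length=8_000_000,
            n_blocks=30,
            block_length_log_mean=math.log(200_000),
            block_length_log_sd=0.5,
            min_block_length=50_000,
            n_motifs=4,
            n_genes=10,
        )
        defaults.update(kw)
        return cls(**defaults)

    @property
    def resolved_max_block_length(self) -> int:
        return (
            self.max_block_length
            if self.max_block_length is not None
            else self.chrom_length // 10
        )


@dataclass
class TruthRecord:
    """What was planted, sufficient to score recovery downstream."""

    enriched_motifs: list[str]
    planted: pd.DataFrame  # chrom, pos, motif_id, strand, context
    chip_peak_centers: pd.DataFrame  # chrom, center
    hic_intra_boost: float
    tad_jitter_sd: float


@dataclass
class SyntheticBundle:
    config: SimConfig
    genome: Genome
    blocks: RegionSet
    motif_library: list[PWM]
    tss: RegionSet
    cpg_islands: RegionSet
    ctcf_sites: RegionSet
    chip_tracks: dict[str, tuple]  # mark -> (treatment, input) BinnedTrack
    hic: dict[str, HiCMatrix]
    tads: RegionSet
    interactions: InteractionMap
    truth: TruthRecord

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.genome.sizes


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def sample_block_lengths(
    config: SimConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Untruncated lognormal block lengths (the distribution whose closed
    forms the generator's defaults target: mean/median = exp(sd^2/2) ≈ 3.6)."""
    return np.exp(
        rng.normal(config.block_length_log_mean, config.block_length_log_sd, size=n)
    ).astype(np.int64)


def _place_blocks(config: SimConfig, rng: np.random.Generator) -> RegionSet:
    spec = config.boundary_spec
    margin = spec.flank_outside + spec.flank_inside
    pad = spec.flank_outside + spec.flank_inside  # keeps boundary regions disjoint
    max_len = config.resolved_max_block_length
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    per_chrom = [
        config.n_blocks // config.n_chromosomes
        + (1 if i < config.n_blocks % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    intervals: list[GenomicInterval] = []
    for chrom, n_here in zip(chroms, per_chrom):
        placed: list[tuple[int, int]] = []
        attempts = 0
        budget = 30 * max(n_here, 1)
        while len(placed) < n_here:
            if attempts >= budget:
                raise PlacementError(
                    f"could not place {n_here} blocks on {chrom} "
                    f"({len(placed)} placed in {attempts} attempts)",
                    achieved=len(placed),
                )
            attempts += 1
            length = int(sample_block_lengths(config, 1, rng)[0])
            if not config.min_block_length <= length <= max_len:
                continue
            lo, hi = margin, config.chrom_length - margin - length
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + length
            if any(start - pad < pe and ps < end + pad for ps, pe in placed):
                continue
            placed.append((start, end))
        intervals.extend(GenomicInterval(chrom, s, e) for s, e in sorted(placed))
    return RegionSet(intervals, label="block")


def _make_pwms(config: SimConfig, rng: np.random.Generator) -> list[PWM]:
    w_lo, w_hi = config.motif_width_range
    library = []
    for i in range(config.n_motifs):
        width = int(rng.integers(w_lo, w_hi + 1))
        dominant = rng.integers(0, 4, size=width)
        mat = np.full((width, 4), 0.1 / 3)
        mat[np.arange(width), dominant] = 0.9
        library.append(PWM(f"M{i:03d}", mat))
    return library


def _sample_site(pwm: PWM, rng: np.random.Generator) -> np.ndarray:
    return np.array(
        [rng.choice(4, p=pwm.matrix[j]) for j in range(pwm.width)], dtype=np.uint8
    )


def _plant(
    codes: Mapping[str, np.ndarray],
    chrom: str,
    pos: int,
    site: np.ndarray,
    strand: str,
) -> None:
    if strand == "-":
        site = site[::-1]
        site = np.array([3, 2, 1, 0, 4], dtype=np.uint8)[site]
    codes[chrom][pos : pos + len(site)] = site


def simulate_bundle(config: SimConfig) -> SyntheticBundle:
    """Generate the full input bundle for one seed (see module docstring)."""
    rngs = _rngs(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = {
        c: rngs["genome"].choice(4, size=config.chrom_length, p=base_p).astype(np.uint8)
        for c in chroms
    }
    sizes = {c: config.chrom_length for c in chroms}

    blocks = _place_blocks(config, rngs["blocks"])
    boundaries = derive_boundaries(blocks, config.boundary_spec, sizes)
    region_len = config.boundary_spec.region_length
    edge_offset = config.boundary_spec.flank_outside

    library = _make_pwms(config, rngs["motifs"])
    n_enriched = int(round(config.boundary_enriched_fraction * config.n_motifs))
    enriched_ids = sorted(
        library[i].motif_id
        for i in rngs["motifs"].choice(config.n_motifs, size=n_enriched, replace=False)
    )
    enriched = set(enriched_ids)

    rng_p = rngs["planting"]
    planted_rows: list[dict] = []
    for pwm in library:
        # genome-wide background occurrences, expected rate per 6 kb
        for chrom in chroms:
            lam = config.background_planting_rate * sizes[chrom] / region_len
            n_bg = rng_p.poisson(lam)
            for _ in range(n_bg):
                pos = int(rng_p.integers(0, sizes[chrom] - pwm.width))
                strand = "+" if rng_p.random() < 0.5 else "-"
                _plant(codes, chrom, pos, _sample_site(pwm, rng_p), strand)
                planted_rows.append(
                    dict(chrom=chrom, pos=pos, motif_id=pwm.motif_id, strand=strand,
                         context="background")
                )
    extra_rate = config.boundary_planting_rate - config.background_planting_rate
    for pwm in library:
        if pwm.motif_id not in enriched or extra_rate <= 0:
            continue
        for iv, meta in zip(boundaries.intervals, boundaries.meta):
            n_here = rng_p.poisson(extra_rate)
            for _ in range(n_here):
                # mirrored offset: 0 = outermost end, edge at flank_outside
                o = rng_p.normal(edge_offset, config.boundary_offset_sd)
                o = int(np.clip(o, 0, region_len - pwm.width))
                raw = o if meta["side"] == "left" else region_len - pwm.width - o
                pos = iv.start + raw
                strand = "+" if rng_p.random() < 0.5 else "-"
                _plant(codes, chrom := iv.chrom, pos, _sample_site(pwm, rng_p), strand)
                planted_rows.append(
                    dict(chrom=chrom, pos=pos, motif_id=pwm.motif_id, strand=strand,
                         context="boundary")
                )
    planted = pd.DataFrame(
        planted_rows, columns=["chrom", "pos", "motif_id", "strand", "context"]
    )

    genome = Genome(codes)

    # CpG islands: a fraction of block edges, plus scattered background islands
    rng_c = rngs["cpg"]
    cpg_iv: list[GenomicInterval] = []
    half = config.cpg_island_length // 2
    for block in blocks:
        for edge in (block.start, block.end):
            if rng_c.random() < config.cpg_island_fraction:
                s = max(0, edge - half)
                cpg_iv.append(GenomicInterval(block.chrom, s, s + config.cpg_island_length))
    for _ in range(max(1, config.n_blocks // 5)):
        chrom = chroms[int(rng_c.integers(0, len(chroms)))]
        s = int(rng_c.integers(0, sizes[chrom] - config.cpg_island_length))
        cpg_iv.append(GenomicInterval(chrom, s, s + config.cpg_island_length))
    cpg_islands = RegionSet(_merge(cpg_iv), label="cpg")

    # CTCF sites
    rng_t = rngs["ctcf"]
    ctcf_iv: list[GenomicInterval] = []
    for iv in boundaries:
        if rng_t.random() < config.ctcf_boundary_prob:
            s = int(rng_t.integers(iv.start, iv.end - config.ctcf_site_length))
            ctcf_iv.append(GenomicInterval(iv.chrom, s, s + config.ctcf_site_length))
    for chrom in chroms:
        lam = config.ctcf_background_prob * sizes[chrom] / region_len
        for _ in range(rng_t.poisson(lam)):
            s = int(rng_t.integers(0, sizes[chrom] - config.ctcf_site_length))
            ctcf_iv.append(GenomicInterval(chrom, s, s + config.ctcf_site_length))
    ctcf_sites = RegionSet(ctcf_iv, label="ctcf")

    # ChIP tracks: peaked promoter-like mark + flat control mark
    from .signal import BinnedTrack  # local import avoids a cycle at import time

    rng_chip = rngs["chip"]
    bw = config.chip_bin_width
    peak_centers: list[dict] = []
    lam_peak: dict[str, np.ndarray] = {}
    for chrom in chroms:
        n_bins = sizes[chrom] // bw
        lam = np.full(n_bins, config.chip_background, dtype=float)
        centers = []
        for block in blocks:
            if block.chrom != chrom:
                continue
            for edge, sign in ((block.start, -1), (block.end, +1)):
                center = edge + sign * abs(config.chip_peak_offset)
                centers.append(center)
                peak_centers.append(dict(chrom=chrom, center=int(center)))
        x = (np.arange(n_bins) + 0.5) * bw
        for c in centers:
            lam += config.chip_peak_height * np.exp(
                -((x - c) ** 2) / (2 * config.chip_peak_sd**2)
            )
        lam_peak[chrom] = lam
    chip_tracks: dict[str, tuple] = {}
    flat = {
        c: np.full(sizes[c] // bw, config.chip_background, dtype=float) for c in chroms
    }
    for mark, lam_map in (("H3K4me3", lam_peak), ("H3K27me3", flat)):
        treat = {c: rng_chip.poisson(lam_map[c]).astype(float) for c in chroms}
        inp = {
            c: rng_chip.poisson(np.full_like(lam_map[c], config.chip_background)).astype(float)
            for c in chroms
        }
        chip_tracks[mark] = (BinnedTrack(treat, bw), BinnedTrack(inp, bw))

    # Hi-C matrices with intra-block lift
    rng_h = rngs["hic"]
    hic: dict[str, HiCMatrix] = {}
    for chrom in chroms:
        n_bins = -(-sizes[chrom] // config.hic_bin_width)
        a = rng_h.exponential(config.hic_background_mean, size=(n_bins, n_bins))
        m = (a + a.T) / 2
        matrix = HiCMatrix(chrom=chrom, matrix=m, bin_width=config.hic_bin_width)
        if config.hic_intra_boost > 0:
            mapping, _ = map_blocks_to_bins(blocks, matrix)
            for bins in mapping.values():
                for ii, bi in enumerate(bins):
                    for bj in bins[ii + 1 :]:
                        matrix.matrix[bi, bj] += config.hic_intra_boost
                        matrix.matrix[bj, bi] += config.hic_intra_boost
        hic[chrom] = matrix

    # TADs: jittered block edges, or unrelated random blocks under the null
    rng_tad = rngs["tads"]
    if math.isinf(config.tad_jitter_sd):
        tads = RegionSet(
            _random_length_matched(blocks, sizes, rng_tad).intervals, label="tad"
        )
    else:
        tad_iv = []
        for block in blocks:
            s = int(round(block.start + rng_tad.normal(0, config.tad_jitter_sd)))
            e = int(round(block.end + rng_tad.normal(0, config.tad_jitter_sd)))
            s = max(0, min(s, sizes[block.chrom] - 2))
            e = max(s + 1, min(e, sizes[block.chrom]))
            tad_iv.append(GenomicInterval(block.chrom, s, e))
        tads = RegionSet(tad_iv, label="tad")

    # TSS for the promoter class, outside blocks and boundaries
    rng_g = rngs["genes"]
    tss_iv: list[GenomicInterval] = []
    promoter_windows: list[GenomicInterval] = []
    attempts, budget = 0, 30 * config.n_genes
    up, down = (
        config.boundary_spec.flank_outside,
        config.boundary_spec.flank_inside,
    )
    while len(tss_iv) < config.n_genes and attempts < budget:
        attempts += 1
        chrom = chroms[int(rng_g.integers(0, len(chroms)))]
        pos = int(rng_g.integers(up + 1, sizes[chrom] - up - 1))
        strand = "+" if rng_g.random() < 0.5 else "-"
        if strand == "+":
            win = GenomicInterval(chrom, pos - up, pos + down)
        else:
            win = GenomicInterval(chrom, pos - down, pos + up)
        if blocks.any_overlap(win) or boundaries.any_overlap(win):
            continue
        if any(win.overlaps(w) for w in promoter_windows):
            continue
        promoter_windows.append(win)
        tss_iv.append(GenomicInterval(chrom, pos, pos + 1, strand))
    tss = RegionSet(tss_iv, label="tss")

    # interaction map wired preferentially to the planted motifs
    rng_m = rngs["cme"]
    cme_genes = {f"CME{i:04d}" for i in range(config.n_cme_genes)}
    pool = [f"GENE{i:04d}" for i in range(200)]
    motif_gene = {p.motif_id: f"TF_{p.motif_id}" for p in library}
    interactions: dict[str, set[str]] = {}
    cme_sorted = sorted(cme_genes)
    for pwm in library:
        gene = motif_gene[pwm.motif_id]
        p_link = (
            config.cme_prob_enriched
            if pwm.motif_id in enriched
            else config.cme_prob_background
        )
        partners: set[str] = set(
            rng_m.choice(pool, size=int(rng_m.integers(0, 3)), replace=False)
        )
        if rng_m.random() < p_link:
            k = int(rng_m.integers(1, 4))
            partners |= set(rng_m.choice(cme_sorted, size=k, replace=False))
        interactions[gene] = partners
    imap = InteractionMap(interactions, cme_genes, motif_gene)

    truth = TruthRecord(
        enriched_motifs=enriched_ids,
        planted=planted,
        chip_peak_centers=pd.DataFrame(peak_centers, columns=["chrom", "center"]),
        hic_intra_boost=config.hic_intra_boost,
        tad_jitter_sd=config.tad_jitter_sd,
    )
    return SyntheticBundle(
        config=config,
        genome=genome,
        blocks=blocks,
        motif_library=library,
        tss=tss,
        cpg_islands=cpg_islands,
        ctcf_sites=ctcf_sites,
        chip_tracks=chip_tracks,
        hic=hic,
        tads=tads,
        interactions=imap,
        truth=truth,
    )


def _merge(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            merged[-1] = GenomicInterval(
                iv.chrom, merged[-1].start, max(merged[-1].end, iv.end)
            )
        else:
            merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# bundle serialization
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> pd.DataFrame:
    """Write every input as plain text; returns the manifest (file, sha256),
    also saved as ``manifest.tsv``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.genome.write_fasta(d / "genome.fa")
    write_chrom_sizes(bundle.chrom_sizes, d / "chrom.sizes")
    bundle.blocks.to_bed(d / "blocks.bed")
    bundle.tss.to_bed(d / "tss.bed")
    bundle.cpg_islands.to_bed(d / "cpg_islands.bed")
    bundle.ctcf_sites.to_bed(d / "ctcf.bed")
    bundle.tads.to_bed(d / "tads.bed")
    write_meme(bundle.motif_library, d / "motifs.meme")
    for mark, (treat, inp) in sorted(bundle.chip_tracks.items()):
        treat.to_bedgraph(d / f"chip_{mark}.treatment.bedgraph")
        inp.to_bedgraph(d / f"chip_{mark}.input.bedgraph")
    for chrom, matrix in sorted(bundle.hic.items()):
        matrix.write(d / f"hic_{chrom}")
    bundle.interactions.to_tsv(d)
    bundle.truth.planted.to_csv(d / "truth_planted.tsv", sep="\t", index=False)
    bundle.truth.chip_peak_centers.to_csv(
        d / "truth_chip_peaks.tsv", sep="\t", index=False
    )
    cfg = asdict(bundle.config)
    if math.isinf(cfg["tad_jitter_sd"]):
        cfg["tad_jitter_sd"] = "inf"
    (d / "truth_meta.json").write_text(
        json.dumps(
            {
                "enriched_motifs": bundle.truth.enriched_motifs,
                "hic_intra_boost": bundle.truth.hic_intra_boost,
                "tad_jitter_sd": (
                    "inf" if math.isinf(bundle.truth.tad_jitter_sd)
                    else bundle.truth.tad_jitter_sd
                ),
                "config": cfg,
            },
            indent=2,
            sort_keys=True,
        )
    )
    files = sorted(p for p in d.iterdir() if p.name != "manifest.tsv")
    manifest = pd.DataFrame(
        {"file": [p.name for p in files], "sha256": [_sha256(p) for p in files]}
    )
    manifest.to_csv(d / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_bundle(directory: str | Path) -> SyntheticBundle:
    """Round-trip reader for a written bundle."""
    d = Path(directory)
    meta = json.loads((d / "truth_meta.json").read_text())
    cfg_dict = dict(meta["config"])
    cfg_dict["boundary_spec"] = BoundarySpec(**cfg_dict["boundary_spec"])
    cfg_dict["motif_width_range"] = tuple(cfg_dict["motif_width_range"])
    if cfg_dict["tad_jitter_sd"] == "inf":
        cfg_dict["tad_jitter_sd"] = math.inf
    config = SimConfig(**cfg_dict)
    from .signal import BinnedTrack

    genome = Genome.from_fasta(d / "genome.fa")
    chip_tracks: dict[str, tuple] = {}
    for treat_path in sorted(d.glob("chip_*.treatment.bedgraph")):
        mark = treat_path.name[len("chip_") : -len(".treatment.bedgraph")]
        chip_tracks[mark] = (
            BinnedTrack.from_bedgraph(treat_path, config.chip_bin_width),
            BinnedTrack.from_bedgraph(
                d / f"chip_{mark}.input.bedgraph", config.chip_bin_width
            ),
        )
    hic = {}
    for sidecar in sorted(d.glob("hic_*.json")):
        prefix = str(sidecar)[: -len(".json")]
        m = HiCMatrix.read(prefix)
        hic[m.chrom] = m
    tad_jitter = meta["tad_jitter_sd"]
    truth = TruthRecord(
        enriched_motifs=list(meta["enriched_motifs"]),
        planted=pd.read_csv(d / "truth_planted.tsv", sep="\t"),
        chip_peak_centers=pd.read_csv(d / "truth_chip_peaks.tsv", sep="\t"),
        hic_intra_boost=float(meta["hic_intra_boost"]),
        tad_jitter_sd=math.inf if tad_jitter == "inf" else float(tad_jitter),
    )
    return SyntheticBundle(
        config=config,
        genome=genome,
        blocks=RegionSet.from_bed(d / "blocks.bed", label="block"),
        motif_library=read_meme(d / "motifs.meme"),
        tss=RegionSet.from_bed(d / "tss.bed", label="tss"),
        cpg_islands=RegionSet.from_bed(d / "cpg_islands.bed", label="cpg"),
        ctcf_sites=RegionSet.from_bed(d / "ctcf.bed", label="ctcf"),
        chip_tracks=chip_tracks,
        hic=hic,
        tads=RegionSet.from_bed(d / "tads.bed", label="tad"),
        interactions=InteractionMap.from_tsv(d),
        truth=truth,
    )
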
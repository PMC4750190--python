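"""PWM motif scanning and the motif-count / CpG-fraction feature matrix.

Scanning follows the classical FIMO-style scheme: a position weight matrix
(PWM) is scored against every window of the sequence as a log-odds sum
``score(w) = sum_i log2(p_i(b_i) / bg(b_i))`` in bits, on both strands, and a
window is called a hit when the probability under the background model of a
score at least as large — computed exactly by dynamic-programming convolution
of the per-column score distributions on a discretized score grid — is at or
below ``p_threshold`` (default 1e-4). Overlapping hits of the same motif all
count; windows containing N are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import Genome, encode
from .intervals import RegionSet

DEFAULT_PSEUDOCOUNT = 1e-3
#: score discretization, grid units per bit
SCORE_SCALE = 1000


@dataclass
class PWM:
    """Probability matrix over A/C/G/T columns with a background model.

    ``matrix`` has shape (width, 4), rows summing to 1 after the pseudocount
    is folded in. Scores are log2 odds against ``background``.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if self.width < 2:
            raise ValueError("PWM width must be >= 2")
        m = self.matrix + self.pseudocount
        self.matrix = m / m.sum(axis=1, keepdims=True)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns do not sum to 1")
        self._score_cache: dict | None = None

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """(width, 4) matrix of log2(p/bg) scores in bits."""
        return np.log2(self.matrix / self.background)

    def reverse_complement(self) -> "PWM":
        rc = PWM.__new__(PWM)
        rc.motif_id = self.motif_id
        rc.matrix = self.matrix[::-1, ::-1].copy()
        rc.background = self.background.copy()
        rc.pseudocount = self.pseudocount
        rc._score_cache = None
        return rc

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    # -- exact null distribution -------------------------------------------
    def _score_tables(self):
        """Integer log-odds tables and the exact null survival function.

        Scores are rounded to a grid of ``SCORE_SCALE`` units per bit; the
        null pmf over total integer score is the convolution of the
        per-column distributions under the background, so the returned
        survival function is exact for the discretized score.
        """
        if self._score_cache is not None:
            return self._score_cache
        lo = self.log_odds()
        int_scores = np.rint(lo * SCORE_SCALE).astype(np.int64)  # (w, 4)
        col_min = int_scores.min(axis=1)
        col_max = int_scores.max(axis=1)
        total_min = int(col_min.sum())
        total_max = int(col_max.sum())
        size = total_max - total_min + 1
        pmf = np.zeros(size)
        pmf[0] = 1.0  # offset representation: index = score - running_min
        run_min = 0
        for j in range(self.width):
            new = np.zeros(size)
            for b in range(4):
                shift = int(int_scores[j, b] - col_min[j])
                if self.background[b] > 0:
                    new[shift:] += self.background[b] * pmf[: size - shift or None]
            pmf = new
            run_min += int(col_min[j])
        # survival: P(score_int >= s)
        sf = pmf[::-1].cumsum()[::-1]
        self._score_cache = {
            "int_scores": int_scores,
            "total_min": total_min,
            "sf": sf,
        }
        return self._score_cache

    def pvalue(self, score_bits: float) -> float:
        """Exact background p-value of a log-odds score (in bits)."""
        tab = self._score_tables()
        s = int(np.rint(score_bits * SCORE_SCALE))
        idx = s - tab["total_min"]
        sf = tab["sf"]
        if idx <= 0:
            return 1.0
        if idx >= len(sf):
            return 0.0
        return float(min(sf[idx], 1.0))

    def score_threshold(self, p_threshold: float) -> int:
        """Smallest integer grid score whose p-value is <= p_threshold."""
        tab = self._score_tables()
        sf = tab["sf"]
        ok = np.flatnonzero(sf <= p_threshold)
        if len(ok) == 0:
            return tab["total_min"] + len(sf)  # unreachable score
        return tab["total_min"] + int(ok[0])


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    motif_id: str
    offset: int
    strand: str
    score: float  # bits
    p_value: float


def _scan_codes_one_strand(
    pwm: PWM, codes: np.ndarray, strand: str, region_id: str, p_threshold: float
) -> list[MotifHit]:
    w = pwm.width
    n_pos = len(codes) - w + 1
    if n_pos <= 0:
        return []
    tab = pwm._score_tables()
    int_scores = tab["int_scores"]
    # per-column lookup with N (code 4) poisoned
    lut = np.full((w, 5), np.iinfo(np.int32).min // (w + 1), dtype=np.int64)
    lut[:, :4] = int_scores
    scores = np.zeros(n_pos, dtype=np.int64)
    for j in range(w):
        scores += lut[j][codes[j : j + n_pos]]
    thr = pwm.score_threshold(p_threshold)
    hit_pos = np.flatnonzero(scores >= thr)
    sf = tab["sf"]
    total_min = tab["total_min"]
    hits = []
    for pos in hit_pos:
        s_int = int(scores[pos])
        idx = min(max(s_int - total_min, 0), len(sf) - 1)
        hits.append(
            MotifHit(
                region_id=region_id,
                motif_id=pwm.motif_id,
                offset=int(pos),
                strand=strand,
                score=s_int / SCORE_SCALE,
                p_value=float(min(sf[idx], 1.0)),
            )
        )
    return hits


def scan(
    pwm: PWM,
    sequence: str | np.ndarray,
    p_threshold: float = 1e-4,
    region_id: str = "",
    both_strands: bool = True,
) -> list[MotifHit]:
    """All hits of ``pwm`` in ``sequence`` at the given p-value threshold.

    The reverse strand is scanned by scoring the reverse-complement PWM on
    the forward sequence, so a minus-strand hit's offset is the leftmost base
    of the occupied window in forward coordinates. Windows containing N never
    reach the threshold. Raises on characters outside A/C/G/T/N.
    """
    if isinstance(sequence, str):
        bad = set(sequence.upper()) - set("ACGTN")
        if bad:
            pos = next(i for i, ch in enumerate(sequence.upper()) if ch in bad)
            raise ValueError(f"invalid base {sequence[pos]!r} at position {pos}")
        codes = encode(sequence)
    else:
        codes = np.asarray(sequence, dtype=np.uint8)
        if codes.size and codes.max() > 4:
            pos = int(np.argmax(codes > 4))
            raise ValueError(f"invalid base code at position {pos}")
    hits = _scan_codes_one_strand(pwm, codes, "+", region_id, p_threshold)
    if both_strands:
        hits += _scan_codes_one_strand(
            pwm.reverse_complement(), codes, "-", region_id, p_threshold
        )
    return sorted(hits, key=lambda h: (h.offset, h.strand))


@dataclass
class FeatureMatrix:
    """Regions × (per-motif hit count + cpg_fraction) table with class labels."""

    counts: pd.DataFrame  # index: region ids; columns: motif ids + 'cpg_fraction'
    labels: pd.Series  # aligned with counts.index

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.labels.index):
            raise ValueError("feature rows and labels are misaligned")
        if self.counts.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    @property
    def motif_ids(self) -> list[str]:
        return [c for c in self.counts.columns if c != "cpg_fraction"]

    def classes(self) -> list[str]:
        return sorted(self.labels.unique())

    def subset_classes(self, *classes: str) -> "FeatureMatrix":
        mask = self.labels.isin(classes)
        return FeatureMatrix(self.counts.loc[mask], self.labels.loc[mask])

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "class", self.labels)
        out.to_csv(path, sep="\t", index_label="region_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="region_id")
        labels = df.pop("class")
        return cls(df, labels)


def region_id_of(rs_label: str, i: int) -> str:
    return f"{rs_label}_{i:05d}"


def scan_regions(
    regions: RegionSet,
    library: Sequence[PWM],
    genome: Genome,
    p_threshold: float = 1e-4,
) -> list[MotifHit]:
    """Scan every PWM over every region; region ids are ``<label>_<index>``."""
    hits: list[MotifHit] = []
    seqs = [
        genome.fetch_codes(iv.chrom, iv.start, iv.end) for iv in regions
    ]
    for pwm in library:
        rc = pwm.reverse_complement()
        for i, codes in enumerate(seqs):
            rid = region_id_of(regions.label, i)
            hits += _scan_codes_one_strand(pwm, codes, "+", rid, p_threshold)
            hits += _scan_codes_one_strand(rc, codes, "-", rid, p_threshold)
    return hits


def build_features(
    regions: RegionSet,
    library: Sequence[PWM],
    cpg: RegionSet,
    genome: Genome,
    p_threshold: float = 1e-4,
    hits: Iterable[MotifHit] | None = None,
) -> FeatureMatrix:
    """Per-region motif hit counts plus the CpG-island overlap fraction.

    All regions must share one length. Overlapping hits each count. The
    final column ``cpg_fraction`` is overlapped bases / region length.
    Precomputed ``hits`` (e.g. from an external FIMO run) may be supplied to
    bypass the internal scanner.
    """
    lengths = {iv.length for iv in regions}
    if len(lengths) > 1:
        raise ValueError(f"regions have mixed lengths: {sorted(lengths)}")
    region_len = lengths.pop() if lengths else 0
    ids = [region_id_of(regions.label, i) for i in range(len(regions))]
    motif_ids = [p.motif_id for p in library]
    counts = pd.DataFrame(0, index=ids, columns=motif_ids, dtype=int)
    if hits is None:
        hits = scan_regions(regions, library, genome, p_threshold)
    pairs = [
        (h.region_id, h.motif_id)
        for h in hits
        if h.region_id in counts.index and h.motif_id in counts.columns
    ]
    if pairs:
        hdf = pd.DataFrame(pairs, columns=["region_id", "motif_id"])
        tab = pd.crosstab(hdf["region_id"], hdf["motif_id"])
        counts = counts.add(
            tab.reindex(index=counts.index, columns=counts.columns, fill_value=0),
            fill_value=0,
        ).astype(int)
    cpg_frac = []
    for iv in regions:
        overlap = sum(iv.overlap_length(c) for c in cpg)
        cpg_frac.append(overlap / region_len if region_len else 0.0)
    counts = pd.concat(
        [counts, pd.DataFrame({"cpg_fraction": cpg_frac}, index=counts.index)], axis=1
    )
    labels = pd.Series(regions.label, index=counts.index, name="class")
    return FeatureMatrix(counts, labels)


def concat_features(*parts: FeatureMatrix) -> FeatureMatrix:
    counts = pd.concat([p.counts for p in parts])
    labels = pd.concat([p.labels for p in parts])
    return FeatureMatrix(counts, labels)


# ---------------------------------------------------------------------------
# MEME minimal format I/O
# ---------------------------------------------------------------------------

def write_meme(library: Sequence[PWM], path: str | Path) -> None:
    """Write PWMs in MEME minimal motif format."""
    with Path(path).open("w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = library[0].background if library else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.6f} C {:.6f} G {:.6f} T {:.6f}\n\n".format(*bg)
        )
        for pwm in library:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.12f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path, pseudocount: float = 0.0) -> list[PWM]:
    """Read a MEME minimal motif file.

    Parsed directly (not via Bio.motifs, whose minimal parser quantizes the
    probabilities to integer counts) so that a write→read round trip
    reproduces the stored matrix to full printed precision. ``pseudocount``
    defaults to 0 because stored probabilities already include the scan
    pseudocount.
    """
    background = np.full(4, 0.25)
    library: list[PWM] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            fields = lines[i + 1].split()
            freqs = {fields[j]: float(fields[j + 1]) for j in range(0, len(fields), 2)}
            background = np.array([freqs[b] for b in "ACGT"])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability matrix"):
                i += 1
            header = dict(
                zip(*(iter(lines[i].split("matrix:")[1].replace("=", " ").split()),) * 2)
            )
            width = int(header["w"])
            rows = [
                [float(v) for v in lines[i + 1 + j].split()] for j in range(width)
            ]
            library.append(
                PWM(motif_id, np.array(rows), background=background,
                    pseudocount=pseudocount)
            )
            i += 1 + width
            continue
        i += 1
    if not library:
        raise ValueError(f"no motifs found in {path}")
    return library


def hits_to_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    df = pd.DataFrame([h.__dict__ for h in hits])
    if df.empty:
        df = pd.DataFrame(
            columns=["region_id", "motif_id", "offset", "strand", "score", "p_value"]
        )
    df.to_csv(path, sep="\t", index=False)


def hits_from_tsv(path: str | Path) -> list[MotifHit]:
    """Read a FIMO-style hit table (as written by :func:`hits_to_tsv`)."""
    df = pd.read_csv(path, sep="\t")
    return [
        MotifHit(
            region_id=str(r.region_id),
            motif_id=str(r.motif_id),
            offset=int(r.offset),
            strand=str(r.strand),
            score=float(r.score),
            p_value=float(r.p_value),
        )
        for r in df.itertuples()
    ]
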
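"""Fisher's exact enrichment tests.

Two families of 2×2 tables are tested:

* per-motif presence (count >= 1) in boundary regions versus a control
  class — a motif is called *enriched* when the sample odds ratio ad/bc
  exceeds 2 and *depleted* below 0.5;
* chromatin-modification-enzyme (CME) involvement among the top
  discriminating motifs versus the remaining motif background, where a motif
  counts as CME-linked when its TF gene is itself a CME or interacts with at
  least one CME.

P-values are two-sided Fisher exact (scipy). The odds ratio reported is the
sample ratio ad/bc — not the conditional MLE — because the 2/0.5 calling
thresholds are plain odds-ratio bounds; zero cells get the Haldane 0.5
correction and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from .motifs import FeatureMatrix

ENRICHED_OR = 2.0
DEPLETED_OR = 0.5


@dataclass
class ContingencyResult:
    a: int  # positives with the attribute
    b: int  # positives without
    c: int  # controls with
    d: int  # controls without
    odds_ratio: float = field(init=False)
    p_value: float = field(init=False)
    call: str = field(init=False)
    haldane: bool = field(init=False)

    def __post_init__(self) -> None:
        a, b, c, d = self.a, self.b, self.c, self.d
        if min(a, b, c, d) < 0:
            raise ValueError("contingency counts must be non-negative")
        self.haldane = 0 in (a, b, c, d)
        if self.haldane:
            ah, bh, ch, dh = (x + 0.5 for x in (a, b, c, d))
        else:
            ah, bh, ch, dh = a, b, c, d
        self.odds_ratio = (ah * dh) / (bh * ch)
        _, self.p_value = sps.fisher_exact([[a, c], [b, d]], alternative="two-sided")
        if self.odds_ratio > ENRICHED_OR:
            self.call = "enriched"
        elif self.odds_ratio < DEPLETED_OR:
            self.call = "depleted"
        else:
            self.call = "neutral"

    def as_row(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "call": self.call,
            "haldane": self.haldane,
        }


@dataclass
class InteractionMap:
    """TF gene → interacting-partner genes, plus the CME gene set and the
    motif → TF-gene mapping (one shared id namespace)."""

    interactions: Mapping[str, set[str]]
    cme_genes: set[str]
    motif_gene: Mapping[str, str]

    def is_cme_linked(self, motif_id: str) -> bool | None:
        """True if the motif's TF is a CME or interacts with one; None when
        the motif has no gene mapping."""
        gene = self.motif_gene.get(motif_id)
        if gene is None:
            return None
        if gene in self.cme_genes:
            return True
        partners = self.interactions.get(gene, set())
        return bool(partners & self.cme_genes)

    def to_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        with (directory / "interactions.tsv").open("w") as fh:
            for gene in sorted(self.interactions):
                for partner in sorted(self.interactions[gene]):
                    fh.write(f"{gene}\t{partner}\n")
        (directory / "cme_genes.tsv").write_text(
            "".join(f"{g}\n" for g in sorted(self.cme_genes))
        )
        with (directory / "motif_genes.tsv").open("w") as fh:
            for motif in sorted(self.motif_gene):
                fh.write(f"{motif}\t{self.motif_gene[motif]}\n")

    @classmethod
    def from_tsv(cls, directory: str | Path) -> "InteractionMap":
        directory = Path(directory)
        interactions: dict[str, set[str]] = {}
        for line in (directory / "interactions.tsv").read_text().splitlines():
            if not line.strip():
                continue
            gene, partner = line.split("\t")
            interactions.setdefault(gene, set()).add(partner)
        cme = {
            line.strip()
            for line in (directory / "cme_genes.tsv").read_text().splitlines()
            if line.strip()
        }
        motif_gene: dict[str, str] = {}
        for line in (directory / "motif_genes.tsv").read_text().splitlines():
            if not line.strip():
                continue
            motif, gene = line.split("\t")
            motif_gene[motif] = gene
        return cls(interactions, cme, motif_gene)


def motif_enrichment(
    features_case: FeatureMatrix,
    features_control: FeatureMatrix,
    motif_id: str,
) -> ContingencyResult:
    """Presence/absence Fisher table for one motif: a/b over case regions,
    c/d over control regions; presence means hit count >= 1."""
    if len(features_case.counts) == 0 or len(features_control.counts) == 0:
        raise ValueError("empty region set in enrichment test")
    case = features_case.counts[motif_id].to_numpy() >= 1
    ctrl = features_control.counts[motif_id].to_numpy() >= 1
    return ContingencyResult(
        a=int(case.sum()),
        b=int((~case).sum()),
        c=int(ctrl.sum()),
        d=int((~ctrl).sum()),
    )


def enrichment_table(
    features_case: FeatureMatrix,
    features_control: FeatureMatrix,
    motif_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-motif enrichment results, with a Benjamini-Hochberg adjusted
    p-value column added for transparency (no filtering uses it)."""
    ids = list(motif_ids) if motif_ids is not None else features_case.motif_ids
    rows = {
        m: motif_enrichment(features_case, features_control, m).as_row() for m in ids
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "motif"
    df["p_bh"] = sps.false_discovery_control(df["p_value"], method="bh")
    return df


def select_discriminating(
    importance_rank: Sequence[str],
    enrichments: pd.DataFrame,
    k: int,
) -> tuple[list[str], int]:
    """Top-k motifs by importance, filtered to those called enriched in the
    boundary; returns the filtered list and the number discarded."""
    top = list(importance_rank[:k])
    missing = [m for m in top if m not in enrichments.index]
    if missing:
        raise ValueError(f"no enrichment computed for {missing[:3]}...")
    kept = [m for m in top if enrichments.loc[m, "call"] == "enriched"]
    return kept, len(top) - len(kept)


def cme_enrichment(
    selected: Iterable[str],
    interactions: InteractionMap,
    background: Iterable[str],
) -> ContingencyResult:
    """CME-linkage Fisher table: selected motifs vs all other motifs.

    A motif is positive when its TF gene is annotated as a CME or interacts
    with at least one CME. Motifs without a gene mapping are excluded (and
    counted in neither margin).
    """
    selected = set(selected)
    rest = [m for m in background if m not in selected]
    a = b = c = d = 0
    skipped = 0
    for motif in sorted(selected):
        linked = interactions.is_cme_linked(motif)
        if linked is None:
            skipped += 1
        elif linked:
            a += 1
        else:
            b += 1
    for motif in sorted(rest):
        linked = interactions.is_cme_linked(motif)
        if linked is None:
            skipped += 1
        elif linked:
            c += 1
        else:
            d += 1
    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "cme_enrichment: %d motifs without gene mapping excluded", skipped
        )
    return ContingencyResult(a=a, b=b, c=c, d=d)


def cme_sweep(
    importance_rank: Sequence[str],
    interactions: InteractionMap,
    background: Iterable[str],
    k_values: Sequence[int] = (20, 25, 40, 50),
) -> pd.DataFrame:
    """OR / p-value of CME enrichment for each top-k cut of the importance
    ranking (one row per k)."""
    background = list(background)
    rows = []
    for k in k_values:
        kk = min(k, len(importance_rank))
        res = cme_enrichment(importance_rank[:kk], interactions, background)
        rows.append({"k": k, **res.as_row()})
    return pd.DataFrame(rows).set_index("k")
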
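"""Positional classification of lncRNAs against coding-gene annotation.

A lncRNA gene is classified by where it lies relative to protein-coding
genes: SENSE (overlaps a coding exon, same strand), ANTISENSE (overlaps a
coding gene on the opposite strand), INTRONIC (wholly inside one intron,
either strand, no exon overlap), BIDIRECTIONAL (head-to-head 5' ends within
1 kb, no overlap), INTERGENIC (no overlap, >= 1 kb from the nearest coding
gene), else UNCLASSIFIED. When several rules fire the precedence is
SENSE > ANTISENSE > INTRONIC > BIDIRECTIONAL > INTERGENIC.

Coordinates are 0-based half-open genomic intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

__all__ = ["GeneModel", "LncClass", "classify_lncrna", "classify_many",
           "read_gene_models_gtf"]


class LncClass(Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"
    INTRONIC = "intronic"
    BIDIRECTIONAL = "bidirectional"
    INTERGENIC = "intergenic"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GeneModel:
    """Gene span with exons on a genomic coordinate system."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    coding: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("invalid gene span")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        prev = self.start
        for s, e in exons:
            if s < prev or e > self.end or s >= e:
                raise ValueError("exons must be sorted, disjoint and inside the span")
            prev = e
        object.__setattr__(self, "exons", exons or ((self.start, self.end),))

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]))

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


def _overlap(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def _distance(a0: int, a1: int, b0: int, b1: int) -> int:
    if _overlap(a0, a1, b0, b1):
        return 0
    return b0 - a1 if b0 >= a1 else a0 - b1


def classify_lncrna(lnc: GeneModel, coding_genes,
                    proximity: int = 1000,
                    antisense_exon_only: bool = False) -> LncClass:
    """Classify one lncRNA gene; deterministic and order-independent."""
    same_chrom = [g for g in coding_genes if g.coding and g.chrom == lnc.chrom]

    sense = antisense = intronic = bidirectional = False
    min_dist: int | None = None
    for g in same_chrom:
        dist = _distance(lnc.start, lnc.end, g.start, g.end)
        min_dist = dist if min_dist is None else min(min_dist, dist)
        overlaps_gene = dist == 0
        exon_overlap = overlaps_gene and any(
            _overlap(lnc.start, lnc.end, s, e) for s, e in g.exons)
        if overlaps_gene and g.strand == lnc.strand and exon_overlap:
            sense = True
        if overlaps_gene and g.strand != lnc.strand and (
                exon_overlap or not antisense_exon_only):
            antisense = True
        if overlaps_gene and not exon_overlap and any(
                s <= lnc.start and lnc.end <= e for s, e in g.introns):
            intronic = True
        if not overlaps_gene and g.strand != lnc.strand:
            # head-to-head: adjacent 5' ends, transcription divergent
            if abs(lnc.tss - g.tss) <= proximity:
                facing = ((lnc.strand == "+" and g.tss <= lnc.tss)
                          or (lnc.strand == "-" and g.tss >= lnc.tss))
                if facing:
                    bidirectional = True

    if sense:
        return LncClass.SENSE
    if antisense:
        return LncClass.ANTISENSE
    if intronic:
        return LncClass.INTRONIC
    if bidirectional:
        return LncClass.BIDIRECTIONAL
    if min_dist is None or min_dist >= proximity:
        return LncClass.INTERGENIC
    return LncClass.UNCLASSIFIED


def classify_many(lncs, coding_genes, **kwargs) -> pd.DataFrame:
    coding = list(coding_genes)
    return pd.DataFrame({
        "transcript_id": [g.gene_id for g in lncs],
        "lnc_class": [classify_lncrna(g, coding, **kwargs).value for g in lncs],
    })


def read_gene_models_gtf(path, coding_feature: str = "CDS") -> list[GeneModel]:
    """Minimal GTF/GFF reader: exon lines grouped by gene_id.

    A gene is marked coding when any of its lines carries ``coding_feature``.
    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    """
    import re

    genes: dict[str, dict] = {}
    attr_re = re.compile(r'gene_id[ =]"?([^";]+)"?')
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, feature, start, end, _, strand = f[:7]
            m = attr_re.search(f[8])
            if m is None:
                continue
            gid = m.group(1)
            g = genes.setdefault(gid, {"chrom": chrom, "strand": strand,
                                       "exons": [], "coding": False})
            iv = (int(start) - 1, int(end))
            if feature == "exon":
                g["exons"].append(iv)
            if feature == coding_feature:
                g["coding"] = True
    out = []
    for gid, g in genes.items():
        exons = sorted(g["exons"]) or []
        start = min(s for s, _ in exons) if exons else 0
        end = max(e for _, e in exons) if exons else 0
        out.append(GeneModel(gid, g["chrom"], g["strand"], start, end,
                             tuple(exons), g["coding"]))
    return out
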
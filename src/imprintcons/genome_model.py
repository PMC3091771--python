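"""Merged gene models and chromosome partitioning.

A gene is represented by the union of its annotated transcripts: the span runs
from the most 5' transcriptional start site to the most 3' termination site,
exons of all splice variants are merged, and the coding region is the largest
cover of all CDS annotations.  The DNA between two neighbouring genes is cut
in half at the midpoint and each half assigned to the nearer gene, so that
every intergenic base belongs to exactly one gene.  Promoters are the 1000 bp
upstream of the most upstream TSS, strand-aware, clipped only at chromosome
bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import intervals as iv

AUTOSOMAL = "autosomal"
PROMOTER_LENGTH = 1000


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript (0-based half-open coordinates)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: empty transcript span")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside transcript span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.gene_id}: cds_start/cds_end must both be set or both absent")
        if self.cds_start is not None:
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise ValueError(f"{self.gene_id}: CDS span outside transcript span")

    @property
    def coding_intervals(self) -> list[tuple[int, int]]:
        """Exon pieces inside the CDS span (thickStart/thickEnd semantics)."""
        if self.cds_start is None:
            return []
        out = []
        for s, e in self.exons:
            c = iv.clip((s, e), self.cds_start, self.cds_end)
            if c:
                out.append(c)
        return out


@dataclass
class GeneModel:
    """Merged per-gene structure over all transcripts of one gene."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    merged_exons: list[tuple[int, int]]
    merged_coding: list[tuple[int, int]]
    group: str = AUTOSOMAL

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return iv.subtract((self.start, self.end), self.merged_exons)

    @property
    def is_intronless(self) -> bool:
        return not self.introns

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exon_boundaries(self) -> list[int]:
        return sorted({c for s, e in self.merged_exons for c in (s, e)})


@dataclass(frozen=True)
class IntergenicRegion:
    chrom: str
    start: int
    end: int
    assigned_gene_id: str | None
    side: str  # "upstream" / "downstream" relative to the assigned gene's position

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    chrom: str
    start: int
    end: int
    clipped: bool = False


def merge_transcripts(records: Sequence[TranscriptRecord]) -> GeneModel:
    """Collapse all transcripts of one gene into a single merged model.

    The span covers the most 5' start to the most 3' end; exons and CDS
    intervals are interval-unioned across transcripts; introns are the span
    minus the merged exons.

    Raises
    ------
    ValueError
        If records are empty or mix gene ids, chromosomes, or strands.
    """
    if not records:
        raise ValueError("merge_transcripts: empty record list")
    first = records[0]
    for r in records[1:]:
        if r.gene_id != first.gene_id:
            raise ValueError(f"mixed gene ids: {first.gene_id} vs {r.gene_id}")
        if r.chrom != first.chrom:
            raise ValueError(f"{first.gene_id}: transcripts on different chromosomes "
                             f"({first.chrom} vs {r.chrom})")
        if r.strand != first.strand:
            raise ValueError(f"{first.gene_id}: transcripts on different strands")
    start = min(r.tx_start for r in records)
    end = max(r.tx_end for r in records)
    merged_exons = iv.union(ex for r in records for ex in r.exons)
    merged_coding = iv.union(c for r in records for c in r.coding_intervals)
    return GeneModel(first.gene_id, first.chrom, first.strand, start, end,
                     merged_exons, merged_coding)


def build_gene_models(
    transcripts: Iterable[TranscriptRecord],
    groups: Mapping[str, str] | None = None,
) -> dict[str, GeneModel]:
    """Merge transcripts gene-by-gene and attach group labels.

    Genes absent from ``groups`` default to ``autosomal``.
    """
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    models = {}
    for gid, recs in by_gene.items():
        m = merge_transcripts(recs)
        if groups:
            m.group = groups.get(gid, AUTOSOMAL)
        models[gid] = m
    return models


def partition_intergenic(
    genes: Sequence[GeneModel], chrom_length: int
) -> list[IntergenicRegion]:
    """Halve the DNA between consecutive genes and assign each half to the
    nearer gene.

    ``genes`` must be on one chromosome, sorted by start.  Odd-length gaps
    give the extra base to the lower-coordinate gene (floor midpoint).
    Terminal segments before the first and after the last gene go entirely to
    that gene.  Overlapping gene spans produce an empty gap.  The emitted
    regions tile the chromosome minus the union of gene spans exactly.
    """
    if not genes:
        return []
    chroms = {g.chrom for g in genes}
    if len(chroms) > 1:
        raise ValueError(f"genes from multiple chromosomes: {sorted(chroms)}")
    starts = [g.start for g in genes]
    if starts != sorted(starts):
        raise ValueError("genes must be sorted by start coordinate")
    chrom = genes[0].chrom
    out: list[IntergenicRegion] = []
    if genes[0].start > 0:
        out.append(IntergenicRegion(chrom, 0, genes[0].start, genes[0].gene_id, "upstream"))
    # running max end handles nested/overlapping spans: the gap opens only
    # after every span seen so far has closed
    cur_end = genes[0].end
    cur_gene = genes[0]
    for g in genes[1:]:
        gap_start, gap_end = cur_end, g.start
        if gap_end > gap_start:
            mid = (gap_start + gap_end + 1) // 2  # extra base to the left gene
            if mid > gap_start:
                out.append(IntergenicRegion(chrom, gap_start, mid,
                                            cur_gene.gene_id, "downstream"))
            if gap_end > mid:
                out.append(IntergenicRegion(chrom, mid, gap_end,
                                            g.gene_id, "upstream"))
        if g.end > cur_end:
            cur_end = g.end
            cur_gene = g
    if cur_end < chrom_length:
        out.append(IntergenicRegion(chrom, cur_end, chrom_length,
                                    cur_gene.gene_id, "downstream"))
    return out


def promoter_of(gene: GeneModel, chrom_length: int) -> PromoterRegion:
    """1000 bp upstream of the most upstream TSS, strand-aware.

    Clipped only at chromosome bounds (a promoter may overlap a neighbouring
    gene; the definition is purely positional).
    """
    if gene.strand == "+":
        start, end = gene.start - PROMOTER_LENGTH, gene.start
    else:
        start, end = gene.end, gene.end + PROMOTER_LENGTH
    clipped = start < 0 or end > chrom_length
    start = max(start, 0)
    end = min(end, chrom_length)
    return PromoterRegion(gene.gene_id, gene.chrom, start, end, clipped)


def count_intronless(
    genes: Iterable[GeneModel], group: str | None = None
) -> tuple[int, float | None]:
    """Count single-exon genes (optionally within one group).

    Returns ``(count, fraction)``; the fraction is ``None`` for an empty
    selection.
    """
    selected = [g for g in genes if group is None or g.group == group]
    n = len(selected)
    k = sum(g.is_intronless for g in selected)
    return k, (k / n if n else None)
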
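"""Brute-force per-base oracles, independent of the package's interval code.

Everything here works on explicit per-base Python lists so that interval
arithmetic in the package can be checked against an implementation that
cannot share its bugs.
"""

from __future__ import annotations

import numpy as np

from imprintcons.genome_model import GeneModel, TranscriptRecord


def random_gene_fixture(rng: np.random.Generator, chrom_length: int = 8000,
                        max_genes: int = 10, chrom: str = "chrT"):
    """Random non-overlapping gene models on one small chromosome."""
    n_genes = int(rng.integers(1, max_genes + 1))
    genes = []
    pos = int(rng.integers(0, 200))
    for i in range(n_genes):
        n_exons = int(rng.integers(1, 5))
        exons = []
        p = pos
        for j in range(n_exons):
            if j > 0:
                p += int(rng.integers(20, 200))  # intron
            ln = int(rng.integers(20, 150))
            exons.append((p, p + ln))
            p += ln
        if p >= chrom_length - 10:
            break
        cds = None
        if rng.random() < 0.8:
            span = (exons[0][0], exons[-1][1])
            a = int(rng.integers(span[0], span[1] - 1))
            b = int(rng.integers(a + 1, span[1] + 1))
            cds = (a, b)
        merged_coding = []
        if cds:
            for s, e in exons:
                cs, ce = max(s, cds[0]), min(e, cds[1])
                if ce > cs:
                    merged_coding.append((cs, ce))
        genes.append(GeneModel(
            f"g{i}", chrom, "+" if rng.random() < 0.5 else "-",
            exons[0][0], exons[-1][1], exons, merged_coding))
        pos = exons[-1][1] + int(rng.integers(0, 400))
    return genes, chrom_length


def per_base_gene_labels(genes, chrom_length):
    """Per-base (region, owner) labels by brute-force scan.

    region in {coding, exon, intron, intergenic}; owner is the covering gene
    or, for intergenic bases, the nearest gene by gap distance with ties to
    the lower-coordinate gene.
    """
    region = ["intergenic"] * chrom_length
    owner = [None] * chrom_length
    for g in genes:
        for p in range(g.start, g.end):
            owner[p] = g.gene_id
            region[p] = "intron"
        for s, e in g.merged_exons:
            for p in range(s, e):
                region[p] = "exon"
        for s, e in g.merged_coding:
            for p in range(s, e):
                region[p] = "coding"
    ordered = sorted(genes, key=lambda g: (g.start, g.end))
    for p in range(chrom_length):
        if owner[p] is None:
            best = None
            for g in ordered:
                if p < g.start:
                    d = g.start - p
                elif p >= g.end:
                    d = p - g.end + 1
                else:
                    d = 0
                if best is None or d < best[0]:
                    best = (d, g.gene_id)
            owner[p] = best[1] if best else None
    return region, owner


def classify_element_bruteforce(start, end, genes, region, owner):
    """Element class + assigned gene from per-base labels.

    Gene choice: the gene covering the most element bases (tie: lower start);
    class by presence of coding/exon bases of that gene under the element;
    otherwise intergenic, owned by the majority per-base nearest gene
    (tie: the region — equivalently gene — starting lower).
    """
    cover = {}
    for g in genes:
        n = sum(1 for p in range(start, end) if g.start <= p < g.end)
        if n:
            cover[g.gene_id] = n
    if cover:
        ranked = sorted(cover.items(),
                        key=lambda kv: (-kv[1],
                                        [g.start for g in genes
                                         if g.gene_id == kv[0]][0]))
        gid = ranked[0][0]
        gene = next(g for g in genes if g.gene_id == gid)
        has_coding = any(
            any(s <= p < e for s, e in gene.merged_coding)
            for p in range(max(start, gene.start), min(end, gene.end)))
        has_exon = any(
            any(s <= p < e for s, e in gene.merged_exons)
            for p in range(max(start, gene.start), min(end, gene.end)))
        if has_coding:
            cls = "coding"
        elif has_exon:
            cls = "UTR"
        else:
            cls = "intronic"
        return cls, gid
    votes = {}
    first = {}
    for p in range(start, end):
        if 0 <= p < len(owner) and owner[p] is not None:
            votes[owner[p]] = votes.get(owner[p], 0) + 1
            first.setdefault(owner[p], p)
    if not votes:
        return "intergenic", None
    gid = sorted(votes.items(), key=lambda kv: (-kv[1], first[kv[0]]))[0][0]
    return "intergenic", gid


def overlaps_bruteforce(start, end, track):
    """True when >= 1 base of [start,end) is inside any track interval."""
    bases = set()
    for s, e in track:
        bases.update(range(s, e))
    return any(p in bases for p in range(start, end))


def covered_fraction_bruteforce(element_intervals, region_intervals):
    """Fraction of region bases covered by elements, per-base."""
    region_bases = set()
    for s, e in region_intervals:
        region_bases.update(range(s, e))
    if not region_bases:
        return None
    covered = set()
    for s, e in element_intervals:
        covered.update(range(s, e))
    return len(region_bases & covered) / len(region_bases)


def exon_distance_bruteforce(start, end, gene):
    """Signed exon-boundary distance by per-base counting."""
    exonic = set()
    for s, e in gene.merged_exons:
        exonic.update(range(s, e))
    inside = [p for p in range(start, end) if p in exonic]
    if not inside:
        best = None
        for q in exonic:
            d = start - q - 1 if q < start else q - end
            if d < 0:
                continue
            if best is None or d < best:
                best = d
        return best
    # exon-overlapping: penetration depth from the nearest overlapped
    # boundary into the exon
    depths = []
    for es, ee in gene.merged_exons:
        ov = [p for p in range(start, end) if es <= p < ee]
        if not ov:
            continue
        if start >= es and end <= ee:
            depths.append(min(start - es, ee - end))
        else:
            if start < es:
                depths.append(min(end, ee) - es)
            if end > ee:
                depths.append(ee - max(start, es))
    return -min(depths) if depths else None
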
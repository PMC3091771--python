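"""Classification and annotation of conserved elements (PCSs).

A conserved element is assigned to a gene and one of four classes:

* ``coding`` — overlaps a merged coding exon by at least 1 bp;
* ``UTR`` — overlaps a merged exon but no coding base;
* ``intronic`` — inside a gene span with zero exon overlap;
* ``intergenic`` — outside all gene spans, assigned to the gene owning the
  containing intergenic half.

Precedence inside a span is coding > UTR > intronic.  An element overlapping
both a gene span and intergenic DNA follows the genic rule.  Feature overlap
(CpG islands, repeats, TF-binding sites) requires >= 1 bp intersection.
``unique`` elements overlap no exon, repeat, or CpG island — candidate distal
regulatory elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import intervals as iv
from . import seqstats
from .genome_model import AUTOSOMAL, GeneModel, IntergenicRegion, PromoterRegion

MIN_ELEMENT_LENGTH = 20

CODING = "coding"
UTR = "UTR"
INTRONIC = "intronic"
INTERGENIC = "intergenic"

REPEAT_CATEGORIES = (
    "SINE_Alu", "MIR", "L1", "L2", "LTR", "MER", "low_complexity_simple", "other",
)


@dataclass
class ConservedElement:
    """A scored conserved interval (PCS) plus its annotations."""

    chrom: str
    start: int
    end: int
    score: float
    assigned_gene_id: str | None = None
    element_class: str | None = None
    fully_coding: bool = False
    overlap_flags: set[str] = field(default_factory=set)
    first_repeat_category: str | None = None
    unique: bool = False
    group: str = AUTOSOMAL

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class RepeatFeature:
    """A repeat annotation with its family name mapped to a summary category."""

    chrom: str
    start: int
    end: int
    name: str
    rep_class: str = ""

    @property
    def category(self) -> str:
        return repeat_category(self.name, self.rep_class)

    @property
    def is_L1M(self) -> bool:
        return self.name.upper().startswith("L1M")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def repeat_category(name: str, rep_class: str = "") -> str:
    """Map a RepeatMasker family name/class to a summary category.

    ``L1M*`` names form the ancient (mammalian-wide) L1 subgroup but still map
    to ``L1`` here; unknown families map to ``other``.
    """
    n = name.upper()
    c = rep_class.lower()
    if n.startswith("ALU") or c == "sine/alu":
        return "SINE_Alu"
    if n.startswith("MIR") or c == "sine/mir":
        return "MIR"
    if n.startswith("L1") or c == "line/l1":
        return "L1"
    if n.startswith("L2") or c == "line/l2":
        return "L2"
    if n.startswith(("LTR", "MLT", "MST", "ERV", "THE")) or c.startswith("ltr"):
        return "LTR"
    if n.startswith("MER"):
        return "MER"
    if c in ("low_complexity", "simple_repeat") or n.startswith(("(", "GC_RICH", "AT_RICH", "A-RICH")):
        return "low_complexity_simple"
    return "other"


def filter_elements(
    elements: Sequence[ConservedElement], min_len: int = MIN_ELEMENT_LENGTH
) -> tuple[list[ConservedElement], float]:
    """Drop elements shorter than ``min_len`` bp.

    Returns the retained elements and the retention fraction (1.0 for empty
    input).
    """
    kept = [e for e in elements if e.length >= min_len]
    frac = len(kept) / len(elements) if elements else 1.0
    return kept, frac


def _tree(items: Iterable[tuple[int, int, object]]) -> IntervalTree:
    t = IntervalTree()
    for s, e, data in items:
        if e > s:
            t[s:e] = data
    return t


class GenomeAnnotation:
    """Indexed view of gene models + intergenic partition for one genome.

    Built once, queried per element.  ``chrom_lengths`` maps chromosome name
    to length; ``genes`` is a mapping gene_id -> GeneModel.
    """

    def __init__(
        self,
        genes: Mapping[str, GeneModel],
        chrom_lengths: Mapping[str, int],
    ) -> None:
        from .genome_model import partition_intergenic

        self.genes = dict(genes)
        self.chrom_lengths = dict(chrom_lengths)
        self.span_trees: dict[str, IntervalTree] = {}
        self.intergenic: dict[str, list[IntergenicRegion]] = {}
        self.intergenic_trees: dict[str, IntervalTree] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.start, g.end))
            self.span_trees[chrom] = _tree((g.start, g.end, g) for g in gs)
            regions = partition_intergenic(gs, chrom_lengths[chrom])
            self.intergenic[chrom] = regions
            self.intergenic_trees[chrom] = _tree(
                (r.start, r.end, r) for r in regions
            )

    def group_of(self, gene_id: str | None) -> str:
        if gene_id is None or gene_id not in self.genes:
            return AUTOSOMAL
        return self.genes[gene_id].group

    def intergenic_of_gene(self, gene_id: str) -> list[IntergenicRegion]:
        g = self.genes[gene_id]
        return [r for r in self.intergenic.get(g.chrom, ())
                if r.assigned_gene_id == gene_id]


def classify_element(
    element: ConservedElement, annotation: GenomeAnnotation
) -> ConservedElement:
    """Assign gene, class and the fully-coding flag in place (and return it).

    When the element overlaps several gene spans it goes to the gene with the
    larger overlap (ties to the lower-coordinate gene).  Elements on a
    chromosome without genes become intergenic with no assigned gene.
    """
    tree = annotation.span_trees.get(element.chrom)
    hits = sorted(tree[element.start:element.end]) if tree else []
    if hits:
        best = max(
            (h.data for h in hits),
            key=lambda g: (iv.overlap_length(element.interval, g.span), -g.start),
        )
        element.assigned_gene_id = best.gene_id
        if iv.overlap_with_set(element.interval, best.merged_coding) >= 1:
            element.element_class = CODING
            element.fully_coding = iv.contains(best.merged_coding, element.interval)
        elif iv.overlap_with_set(element.interval, best.merged_exons) >= 1:
            element.element_class = UTR
        else:
            element.element_class = INTRONIC
    else:
        element.element_class = INTERGENIC
        itree = annotation.intergenic_trees.get(element.chrom)
        ihits = sorted(itree[element.start:element.end]) if itree else []
        if ihits:
            best_r = max(
                (h.data for h in ihits),
                key=lambda r: (iv.overlap_length(element.interval, (r.start, r.end)),
                               -r.start),
            )
            element.assigned_gene_id = best_r.assigned_gene_id
        else:
            element.assigned_gene_id = None
    element.group = annotation.group_of(element.assigned_gene_id)
    return element


def annotate_overlaps(
    element: ConservedElement,
    tracks: Mapping[str, Mapping[str, IntervalTree]],
) -> ConservedElement:
    """Set one overlap flag per track with >= 1 bp intersection."""
    for name, per_chrom in tracks.items():
        t = per_chrom.get(element.chrom)
        if t is not None and t.overlaps(element.start, element.end):
            element.overlap_flags.add(name)
    return element


def build_track_trees(
    features: Iterable[tuple[str, int, int]] | Iterable[RepeatFeature],
) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees from (chrom, start, end[, ...]) tuples or
    RepeatFeature objects (the tree payload is the feature itself)."""
    per_chrom: dict[str, list] = {}
    for f in features:
        if isinstance(f, RepeatFeature):
            per_chrom.setdefault(f.chrom, []).append((f.start, f.end, f))
        else:
            chrom, s, e = f[0], f[1], f[2]
            per_chrom.setdefault(chrom, []).append((s, e, None))
    return {c: _tree(items) for c, items in per_chrom.items()}


def first_repeat_category(
    element: ConservedElement, repeat_trees: Mapping[str, IntervalTree]
) -> str | None:
    """Category of the overlapping repeat with the smallest start coordinate.

    Ties break by longer overlap, then lexicographic name.  ``None`` when no
    repeat overlaps.
    """
    t = repeat_trees.get(element.chrom)
    if t is None:
        return None
    hits = [h.data for h in t[element.start:element.end]]
    if not hits:
        return None
    best = min(
        hits,
        key=lambda r: (r.start, -iv.overlap_length(element.interval, r.interval), r.name),
    )
    return best.category


def classify_unique(element: ConservedElement) -> bool:
    """Unique = no exon overlap (class intronic or intergenic), no repeat, no
    CpG-island overlap.  Sets and returns the flag."""
    element.unique = (
        element.element_class in (INTRONIC, INTERGENIC)
        and "repeat" not in element.overlap_flags
        and "cpg_island" not in element.overlap_flags
    )
    return element.unique


# ---------------------------------------------------------------------------
# distances, coverage, and track-level summaries
# ---------------------------------------------------------------------------

def signed_exon_distance(
    element: ConservedElement, gene: GeneModel
) -> int | None:
    """Distance from the nearest exon boundary, negative inside exons.

    Purely intronic elements: minimal gap from either element edge to the
    nearest exon boundary of the host gene (0 when abutting).  Exon-
    overlapping elements: negative penetration depth measured from the
    nearest overlapped boundary into the exon; elements fully inside an exon
    use minus the minimal gap to either boundary.  ``None`` when the gene has
    no exons.
    """
    if not gene.merged_exons:
        return None
    s, e = element.start, element.end
    if iv.overlap_with_set(element.interval, gene.merged_exons) == 0:
        best = None
        for b in gene.exon_boundaries:
            d = s - b if b <= s else (b - e if b >= e else 0)
            if best is None or d < best:
                best = d
        return best
    depths = []
    for es, ee in gene.merged_exons:
        if iv.overlap_length((s, e), (es, ee)) == 0:
            continue
        if s >= es and e <= ee:          # fully inside the exon
            depths.append(min(s - es, ee - e))
        else:
            if s < es:                   # crosses the exon start
                depths.append(min(e, ee) - es)
            if e > ee:                   # crosses the exon end
                depths.append(ee - max(s, es))
    return -min(depths) if depths else None


@dataclass
class ExonDistanceProfile:
    """Binned PCS frequency around exon boundaries (Figure-3-style).

    Bin *i* covers distances ``[i*bin_width, (i+1)*bin_width)``; negative bins
    are inside exons.  ``densities`` divide the counts by the number of
    introns in the profiled gene group.
    """

    bin_width: int
    counts: dict[int, int]
    n_introns: int
    n_profiled: int

    @property
    def densities(self) -> dict[int, float]:
        if self.n_introns == 0:
            return {}
        return {b: c / self.n_introns for b, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"bin_start": b * self.bin_width, "count": c,
             "density": c / self.n_introns if self.n_introns else np.nan}
            for b, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["bin_start", "count", "density"])


def exon_distance_profile(
    elements: Iterable[ConservedElement],
    annotation: GenomeAnnotation,
    bin_width: int = 100,
    max_dist: int = 10_000,
    groups: Sequence[str] | None = None,
) -> ExonDistanceProfile:
    """Profile intronic/exon-overlapping elements by distance from the
    nearest exon boundary, normalised by the group's intron count."""
    counts: dict[int, int] = {}
    n_prof = 0
    gene_ids: set[str] = set()
    for el in elements:
        if el.element_class not in (INTRONIC, CODING, UTR):
            continue
        if groups is not None and el.group not in groups:
            continue
        gene = annotation.genes.get(el.assigned_gene_id or "")
        if gene is None:
            continue
        gene_ids.add(gene.gene_id)
        d = signed_exon_distance(el, gene)
        if d is None or abs(d) > max_dist:
            continue
        b = int(np.floor(d / bin_width))
        counts[b] = counts.get(b, 0) + 1
        n_prof += 1
    if groups is None:
        n_introns = sum(len(g.introns) for g in annotation.genes.values())
    else:
        n_introns = sum(
            len(g.introns) for g in annotation.genes.values() if g.group in groups
        )
    return ExonDistanceProfile(bin_width, counts, n_introns, n_prof)


def coverage_summary(
    elements: Iterable[ConservedElement],
    annotation: GenomeAnnotation,
    region_class: str,
) -> pd.DataFrame:
    """Per-gene coverage of a region class by same-class elements.

    For ``intronic``: purely intronic elements against the gene's introns;
    for ``intergenic``: intergenic elements against the gene's assigned
    intergenic halves.  Columns: gene_id, group, region_length,
    covered_fraction, per_10kb.  Genes with a zero-length region class are
    excluded.  Group-level summaries are medians over genes (take them with
    ``df.groupby('group').median()``).
    """
    if region_class not in (INTRONIC, INTERGENIC):
        raise ValueError(f"region_class must be intronic or intergenic, got {region_class}")
    per_gene_elements: dict[str, list[ConservedElement]] = {}
    for el in elements:
        if el.element_class == region_class and el.assigned_gene_id:
            per_gene_elements.setdefault(el.assigned_gene_id, []).append(el)
    rows = []
    for gid, gene in annotation.genes.items():
        if region_class == INTRONIC:
            regions = gene.introns
        else:
            regions = [(r.start, r.end) for r in annotation.intergenic_of_gene(gid)]
        length = iv.total_length(regions)
        if length == 0:
            continue
        els = per_gene_elements.get(gid, [])
        covered_ivs = []
        for el in els:
            for r in regions:
                c = iv.clip(el.interval, r[0], r[1])
                if c:
                    covered_ivs.append(c)
        covered = iv.total_length(iv.union(covered_ivs))
        rows.append({
            "gene_id": gid,
            "group": gene.group,
            "region_length": length,
            "covered_fraction": covered / length,
            "per_10kb": len(els) * 1e4 / length,
        })
    return pd.DataFrame(rows, columns=["gene_id", "group", "region_length",
                                       "covered_fraction", "per_10kb"])


def cgi_conservation_summary(
    islands: Sequence[tuple[str, int, int]],
    elements: Sequence[ConservedElement],
    annotation: GenomeAnnotation | None = None,
    seqs: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Island-level conservation table: overlap with >= 1 element, covered
    fraction, and (when sequence is supplied) the island's deamination index.

    Islands are attributed to the gene whose span (or intergenic half)
    contains them, so downstream group comparisons can be formed.
    """
    el_trees: dict[str, IntervalTree] = {}
    for el in elements:
        el_trees.setdefault(el.chrom, IntervalTree())[el.start:el.end] = el
    rows = []
    for chrom, s, e in islands:
        t = el_trees.get(chrom)
        hits = [h for h in t[s:e]] if t else []
        covered = iv.total_length(iv.union(
            [iv.clip((h.begin, h.end), s, e) for h in hits if iv.clip((h.begin, h.end), s, e)]
        ))
        gene_id = group = None
        if annotation is not None:
            probe = ConservedElement(chrom, s, e, 0.0)
            classify_element(probe, annotation)
            gene_id, group = probe.assigned_gene_id, probe.group
        row = {
            "chrom": chrom, "start": s, "end": e,
            "gene_id": gene_id, "group": group,
            "overlaps_element": bool(hits),
            "covered_fraction": covered / (e - s) if e > s else 0.0,
        }
        if seqs is not None:
            stats = seqstats.composition(str(seqs[chrom])[s:e])
            row["deamination_index"] = stats.deamination_index
            row["cpg_oe"] = stats.cpg_oe
            row["gc"] = stats.gc
        rows.append(row)
    return pd.DataFrame(rows)


def l1_summary(
    repeats: Sequence[RepeatFeature],
    elements: Sequence[ConservedElement],
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """Per-group LINE-1 summary over intergenic regions.

    Columns per group: median L1 coverage fraction of the gene's intergenic
    regions, fraction of L1 repeats containing >= 1 conserved element, and
    the fraction of L1 repeats belonging to the ancient L1M subgroup.
    """
    el_trees: dict[str, IntervalTree] = {}
    for el in elements:
        el_trees.setdefault(el.chrom, IntervalTree())[el.start:el.end] = True
    l1_by_chrom: dict[str, list[RepeatFeature]] = {}
    for r in repeats:
        if r.category == "L1":
            l1_by_chrom.setdefault(r.chrom, []).append(r)

    cover_rows = []
    for gid, gene in annotation.genes.items():
        regions = [(r.start, r.end) for r in annotation.intergenic_of_gene(gid)]
        length = iv.total_length(regions)
        if length == 0:
            continue
        pieces = []
        for r in l1_by_chrom.get(gene.chrom, ()):
            for reg in regions:
                c = iv.clip(r.interval, reg[0], reg[1])
                if c:
                    pieces.append(c)
        cover_rows.append({
            "group": gene.group,
            "l1_coverage": iv.total_length(iv.union(pieces)) / length,
        })
    cover = pd.DataFrame(cover_rows, columns=["group", "l1_coverage"])

    # attribute each L1 repeat to the owning gene group (span or intergenic)
    rep_rows = []
    for chrom, reps in l1_by_chrom.items():
        for r in reps:
            probe = ConservedElement(chrom, r.start, r.end, 0.0)
            classify_element(probe, annotation)
            t = el_trees.get(chrom)
            rep_rows.append({
                "group": probe.group,
                "is_L1M": r.is_L1M,
                "conserved": bool(t is not None and t.overlaps(r.start, r.end)),
            })
    reps_df = pd.DataFrame(rep_rows, columns=["group", "is_L1M", "conserved"])

    groups = sorted(set(cover["group"]).union(reps_df["group"]))
    out = []
    for grp in groups:
        cg = cover[cover["group"] == grp]["l1_coverage"]
        rg = reps_df[reps_df["group"] == grp]
        out.append({
            "group": grp,
            "median_l1_coverage": float(cg.median()) if len(cg) else np.nan,
            "n_l1": len(rg),
            "frac_l1_conserved": float(rg["conserved"].mean()) if len(rg) else np.nan,
            "frac_l1m": float(rg["is_L1M"].mean()) if len(rg) else np.nan,
        })
    return pd.DataFrame(out, columns=["group", "median_l1_coverage", "n_l1",
                                      "frac_l1_conserved", "frac_l1m"])


def gene_site_association(
    annotation: GenomeAnnotation,
    site_tracks: Mapping[str, Sequence[tuple[str, int, int]]],
    promoters: Mapping[str, PromoterRegion] | None = None,
    elements: Sequence[ConservedElement] | None = None,
    require_element_overlap: bool = False,
    region_classes: Sequence[str] = ("intronic", "intergenic", "promoter"),
) -> pd.DataFrame:
    """Per-gene binding-site flags per track and region class, plus the
    co-occurrence of the two tracks anywhere near the gene.

    ``require_element_overlap`` restricts sites to those overlapping >= 1 bp
    of a conserved element (the "conserved binding site" variant).
    Columns: gene_id, group, ``<track>_<region>`` flags, ``<track>_any``, and
    ``co_occurrence`` (all tracks flagged in some region).
    """
    el_trees: dict[str, IntervalTree] = {}
    if elements is not None:
        for el in elements:
            el_trees.setdefault(el.chrom, IntervalTree())[el.start:el.end] = True

    def usable(chrom: str, s: int, e: int) -> bool:
        if not require_element_overlap:
            return True
        t = el_trees.get(chrom)
        return bool(t is not None and t.overlaps(s, e))

    trees: dict[str, dict[str, IntervalTree]] = {}
    for name, sites in site_tracks.items():
        per_chrom: dict[str, list] = {}
        for chrom, s, e in sites:
            if usable(chrom, s, e):
                per_chrom.setdefault(chrom, []).append((s, e, None))
        trees[name] = {c: _tree(items) for c, items in per_chrom.items()}

    def hit(name: str, chrom: str, regions: Sequence[tuple[int, int]]) -> bool:
        t = trees[name].get(chrom)
        if t is None:
            return False
        return any(t.overlaps(s, e) for s, e in regions if e > s)

    rows = []
    for gid, gene in annotation.genes.items():
        row: dict[str, object] = {"gene_id": gid, "group": gene.group}
        region_map: dict[str, list[tuple[int, int]]] = {}
        if "intronic" in region_classes:
            region_map["intronic"] = gene.introns
        if "intergenic" in region_classes:
            region_map["intergenic"] = [
                (r.start, r.end) for r in annotation.intergenic_of_gene(gid)
            ]
        if "promoter" in region_classes and promoters is not None:
            p = promoters.get(gid)
            region_map["promoter"] = [(p.start, p.end)] if p else []
        for name in site_tracks:
            any_hit = False
            for region, regs in region_map.items():
                h = hit(name, gene.chrom, regs)
                row[f"{name}_{region}"] = h
                any_hit = any_hit or h
            row[f"{name}_any"] = any_hit
        row["co_occurrence"] = all(row[f"{name}_any"] for name in site_tracks)
        rows.append(row)
    return pd.DataFrame(rows)


def annotate_elements(
    elements: Sequence[ConservedElement],
    annotation: GenomeAnnotation,
    cpg_islands: Sequence[tuple[str, int, int]] = (),
    repeats: Sequence[RepeatFeature] = (),
    tfbs: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
) -> list[ConservedElement]:
    """Run classification, overlap flagging, first-repeat attribution and the
    unique-element call over a whole element set (in place)."""
    tracks: dict[str, dict[str, IntervalTree]] = {}
    if cpg_islands:
        tracks["cpg_island"] = build_track_trees(cpg_islands)
    repeat_trees = build_track_trees(repeats) if repeats else {}
    if repeats:
        tracks["repeat"] = repeat_trees
    for name, sites in (tfbs or {}).items():
        tracks[f"tfbs_{name}"] = build_track_trees(sites)
    for el in elements:
        classify_element(el, annotation)
        annotate_overlaps(el, tracks)
        if "repeat" in el.overlap_flags:
            el.first_repeat_category = first_repeat_category(el, repeat_trees)
        classify_unique(el)
    return list(elements)


def elements_to_frame(elements: Sequence[ConservedElement]) -> pd.DataFrame:
    """Annotated elements as a flat table (one row per element)."""
    rows = []
    for el in elements:
        rows.append({
            "chrom": el.chrom, "start": el.start, "end": el.end,
            "length": el.length, "score": el.score,
            "gene_id": el.assigned_gene_id, "group": el.group,
            "element_class": el.element_class,
            "fully_coding": el.fully_coding,
            "unique": el.unique,
            "overlaps_cpg_island": "cpg_island" in el.overlap_flags,
            "overlaps_repeat": "repeat" in el.overlap_flags,
            "overlaps_tfbs_yy1": "tfbs_yy1" in el.overlap_flags,
            "overlaps_tfbs_ctcf": "tfbs_ctcf" in el.overlap_flags,
            "first_repeat_category": el.first_repeat_category,
        })
    return pd.DataFrame(rows)


def repeat_category_histogram(
    elements: Sequence[ConservedElement], by_group: bool = True
) -> pd.DataFrame:
    """Counts of repeat-flagged elements per first-overlapping-repeat
    category (Figure-1-style)."""
    rows = [
        {"group": el.group, "category": el.first_repeat_category}
        for el in elements
        if "repeat" in el.overlap_flags and el.first_repeat_category
    ]
    df = pd.DataFrame(rows, columns=["group", "category"])
    keys = ["group", "category"] if by_group else ["category"]
    if df.empty:
        return pd.DataFrame(columns=keys + ["count"])
    return df.groupby(keys).size().reset_index(name="count")
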
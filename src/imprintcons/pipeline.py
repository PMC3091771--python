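"""End-to-end analysis: gene models -> element annotation -> report tables.

``run_analysis`` takes a genome bundle (or the equivalent loose pieces read
from flat files) and produces an :class:`AnalysisResult` holding

* a per-gene feature table and its group-comparison summary (gene-level
  sequence properties: G+C, CpG_obs/CpG_exp, lengths, PCS coverage),
* a per-class conserved-element summary (count, score, length, G+C, CpG
  metrics per element class and gene group),
* k-mer motifs enriched in the labelled groups' elements against both the
  genomic background and the autosomal elements,
* exon-distance profiles, first-repeat-category histograms, CpG-island
  conservation, LINE-1 summaries and per-gene TF-binding-site association.

The analysis itself is deterministic: rerunning on the same inputs writes
byte-identical reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from . import io as io_mod
from . import motif_enrichment, seqstats
from .comparative_stats import compare_continuous, compare_counts, summary_table
from .element_annotator import (
    CODING,
    INTERGENIC,
    INTRONIC,
    UTR,
    ConservedElement,
    GenomeAnnotation,
    RepeatFeature,
    annotate_elements,
    cgi_conservation_summary,
    coverage_summary,
    elements_to_frame,
    exon_distance_profile,
    filter_elements,
    gene_site_association,
    l1_summary,
    repeat_category_histogram,
)
from .genome_model import GeneModel, promoter_of

IMPRINTED = ("maternal", "paternal")


@dataclass
class AnalysisConfig:
    min_element_length: int = 20
    motif_k: int = 6
    motif_threshold: float = 3.5
    motif_class: str = INTRONIC
    motif_pseudocount: float = 1.0
    mask_repeats: bool = False
    profile_bin: int = 100
    profile_max_dist: int = 10_000


@dataclass
class AnalysisResult:
    """All report tables of one pipeline run."""

    config: AnalysisConfig
    gene_features: pd.DataFrame
    table1: pd.DataFrame
    element_table: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    motif_results: list
    retention_fraction: float
    profiles: dict[str, pd.DataFrame]
    repeat_histogram: pd.DataFrame
    cgi_summary: pd.DataFrame
    l1_table: pd.DataFrame
    site_table: pd.DataFrame
    elements: list[ConservedElement] = field(default_factory=list)
    annotation: GenomeAnnotation | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io_mod.write_table(outdir / "gene_features.tsv", self.gene_features)
        io_mod.write_table(outdir / "table1_gene_properties.tsv", self.table1)
        io_mod.write_table(outdir / "table2_element_classes.tsv", self.table2)
        io_mod.write_table(outdir / "table3_enriched_kmers.tsv", self.table3)
        io_mod.write_table(outdir / "element_annotation.tsv", self.element_table)
        for name, prof in self.profiles.items():
            io_mod.write_table(outdir / f"exon_distance_profile_{name}.tsv", prof)
        io_mod.write_table(outdir / "repeat_category_histogram.tsv",
                           self.repeat_histogram)
        io_mod.write_table(outdir / "cpg_island_conservation.tsv", self.cgi_summary)
        io_mod.write_table(outdir / "l1_summary.tsv", self.l1_table)
        io_mod.write_table(outdir / "tfbs_association.tsv", self.site_table)

    def report_text(self) -> str:
        """Human-readable report; stable across reruns on identical input."""
        parts = [
            "# Gene-level sequence properties (medians, stars vs autosomal)",
            self.table1.to_string(index=False),
            "",
            "# Conserved-element classes",
            self.table2.to_string(index=False),
            "",
            "# Enriched k-mers (imprinted vs background and autosomal)",
            self.table3.to_string(index=False),
            "",
            f"# Element length filter retention: {self.retention_fraction:.4f}",
        ]
        return "\n".join(parts) + "\n"


def _gene_feature_frame(
    annotation: GenomeAnnotation,
    seqs: Mapping[str, str],
    elements: Sequence[ConservedElement],
) -> pd.DataFrame:
    """One row per gene with the gene-level sequence properties."""
    cov_intronic = coverage_summary(elements, annotation, INTRONIC)
    cov_intergenic = coverage_summary(elements, annotation, INTERGENIC)
    cov_intronic = cov_intronic.set_index("gene_id")
    cov_intergenic = cov_intergenic.set_index("gene_id")
    rows = []
    for gid, gene in annotation.genes.items():
        stats = seqstats.composition(str(seqs[gene.chrom])[gene.start:gene.end])
        intergenic_len = sum(r.length for r in annotation.intergenic_of_gene(gid))
        introns = gene.introns
        row = {
            "gene_id": gid,
            "group": gene.group,
            "gc": stats.gc,
            "cpg_oe": stats.cpg_oe,
            "gene_length": gene.length,
            "median_intron_length": float(np.median([e - s for s, e in introns]))
            if introns else np.nan,
            "intergenic_length": intergenic_len,
            "is_intronless": gene.is_intronless,
        }
        for name, cov in (("intronic", cov_intronic), ("intergenic", cov_intergenic)):
            if gid in cov.index:
                row[f"{name}_pcs_coverage"] = cov.loc[gid, "covered_fraction"]
                row[f"{name}_pcs_per_10kb"] = cov.loc[gid, "per_10kb"]
            else:
                row[f"{name}_pcs_coverage"] = np.nan
                row[f"{name}_pcs_per_10kb"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


TABLE1_FEATURES = (
    "gc", "cpg_oe", "gene_length", "median_intron_length", "intergenic_length",
    "intronic_pcs_coverage", "intronic_pcs_per_10kb",
    "intergenic_pcs_coverage", "intergenic_pcs_per_10kb",
)


def _element_stats_frame(
    elements: Sequence[ConservedElement], seqs: Mapping[str, str]
) -> pd.DataFrame:
    """Annotated elements + per-element composition statistics."""
    df = elements_to_frame(elements)
    comps = []
    for el in elements:
        st = seqstats.composition(str(seqs[el.chrom])[el.start:el.end])
        comps.append({
            "gc": st.gc,
            "has_cpg": st.has_cpg,
            "cpg_oe": st.cpg_oe,
            "deamination_index": st.deamination_index,
        })
    return pd.concat([df, pd.DataFrame(comps)], axis=1)


ELEMENT_CLASSES = (
    ("cpg_island", "overlaps_cpg_island"),
    ("intronic", None),
    ("intergenic", None),
    ("unique", "unique"),
)


def _table2(element_df: pd.DataFrame) -> pd.DataFrame:
    """Per-class, per-group element summary with stars vs autosomal.

    Classes follow the report layout: elements overlapping CpG islands, the
    intronic class, the intergenic class, and unique elements.
    """
    from .comparative_stats import STAR_NOTATION, significance_tier

    def block_rows(df: pd.DataFrame, block: str) -> list[dict]:
        def members(group: str) -> pd.DataFrame:
            if group == "imprinted":
                return df[df["group"].isin(IMPRINTED)]
            return df[df["group"] == group]

        auto = members("autosomal")
        out = []
        for group in ("imprinted", "maternal", "paternal", "autosomal"):
            sub = members(group)
            row: dict[str, object] = {"block": block, "group": group,
                                      "n": len(sub)}
            if len(sub) == 0:
                out.append(row)
                continue
            cpg_sub = sub[sub["has_cpg"]]
            cpg_auto = auto[auto["has_cpg"]]
            for feat, col, use_cpg in (
                ("score", "score", False),
                ("length", "length", False),
                ("gc", "gc", False),
                ("cpg_oe_cpg", "cpg_oe", True),
                ("deamination_cpg", "deamination_index", True),
            ):
                vals = (cpg_sub if use_cpg else sub)[col].dropna()
                ref = (cpg_auto if use_cpg else auto)[col].dropna()
                row[feat] = float(vals.median()) if len(vals) else np.nan
                if group != "autosomal" and len(vals) and len(ref):
                    cmp = compare_continuous(vals, ref, feature=feat)
                    row[f"{feat}_sig"] = STAR_NOTATION[cmp.tier]
                else:
                    row[f"{feat}_sig"] = ""
            row["frac_with_cpg"] = float(sub["has_cpg"].mean())
            if group != "autosomal" and len(auto):
                cmp = compare_counts(int(sub["has_cpg"].sum()), len(sub),
                                     int(auto["has_cpg"].sum()), len(auto),
                                     feature="frac_with_cpg")
                row["frac_with_cpg_sig"] = STAR_NOTATION[cmp.tier]
            else:
                row["frac_with_cpg_sig"] = ""
            out.append(row)
        return out

    rows: list[dict] = []
    for block, flag in ELEMENT_CLASSES:
        if flag is not None:
            sub = element_df[element_df[flag]]
        else:
            sub = element_df[element_df["element_class"] == block]
        rows.extend(block_rows(sub, block))
    cols = ["block", "group", "n", "score", "score_sig", "length", "length_sig",
            "gc", "gc_sig", "frac_with_cpg", "frac_with_cpg_sig",
            "cpg_oe_cpg", "cpg_oe_cpg_sig",
            "deamination_cpg", "deamination_cpg_sig"]
    return pd.DataFrame(rows, columns=cols)


def _element_sequences_by_gene(
    elements: Sequence[ConservedElement],
    seqs: Mapping[str, str],
    element_class: str,
    groups: Sequence[str],
    mask_repeats: bool = False,
    repeats: Sequence[RepeatFeature] = (),
) -> dict[str, list[str]]:
    rep_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if mask_repeats:
        for r in repeats:
            rep_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        rep_by_chrom = {c: iv.union(v) for c, v in rep_by_chrom.items()}
    out: dict[str, list[str]] = {}
    for el in elements:
        if el.element_class != element_class or el.group not in groups:
            continue
        if el.assigned_gene_id is None:
            continue
        seq = str(seqs[el.chrom])[el.start:el.end]
        if mask_repeats:
            local = [
                (max(0, s - el.start), min(el.length, e - el.start))
                for s, e in rep_by_chrom.get(el.chrom, ())
                if s < el.end and e > el.start
            ]
            seq = motif_enrichment.mask_sequence(seq, local)
        out.setdefault(el.assigned_gene_id, []).append(seq)
    return out


def run_analysis(
    seqs: Mapping[str, str],
    genes: Mapping[str, GeneModel],
    chrom_lengths: Mapping[str, int],
    elements: Sequence[ConservedElement],
    cpg_islands: Sequence[tuple[str, int, int]] = (),
    repeats: Sequence[RepeatFeature] = (),
    tfbs: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisResult:
    """Run the full annotation and comparison pipeline."""
    cfg = config or AnalysisConfig()
    annotation = GenomeAnnotation(genes, chrom_lengths)
    kept, retention = filter_elements(list(elements), cfg.min_element_length)
    annotate_elements(kept, annotation, cpg_islands, repeats, tfbs or {})

    gene_features = _gene_feature_frame(annotation, seqs, kept)
    table1 = summary_table(gene_features, TABLE1_FEATURES)

    element_df = _element_stats_frame(kept, seqs)
    table2 = _table2(element_df)

    # motif enrichment: labelled groups vs genome background and autosomal
    target = _element_sequences_by_gene(
        kept, seqs, cfg.motif_class, IMPRINTED,
        cfg.mask_repeats, repeats)
    comparison = _element_sequences_by_gene(
        kept, seqs, cfg.motif_class, ("autosomal",),
        cfg.mask_repeats, repeats)
    motif_results: list = []
    if target and comparison:
        target_cat = list(motif_enrichment.concatenate_by_gene(target).values())
        comp_cat = list(motif_enrichment.concatenate_by_gene(comparison).values())
        background = [str(seqs[c]) for c in sorted(seqs)]
        motif_results = motif_enrichment.enriched_motifs(
            target_cat, background, comp_cat,
            k=cfg.motif_k, threshold=cfg.motif_threshold,
            pseudocount=cfg.motif_pseudocount)
    table3 = pd.DataFrame(
        [{
            "kmer": m.kmer.lower(),
            "score_vs_genome": m.score_vs_genome,
            "score_vs_comparison": m.score_vs_comparison,
            "contains_cpg": m.contains_cpg,
        } for m in motif_results],
        columns=["kmer", "score_vs_genome", "score_vs_comparison", "contains_cpg"],
    )

    profiles = {
        "imprinted": exon_distance_profile(
            kept, annotation, cfg.profile_bin, cfg.profile_max_dist,
            groups=IMPRINTED).to_frame(),
        "autosomal": exon_distance_profile(
            kept, annotation, cfg.profile_bin, cfg.profile_max_dist,
            groups=("autosomal",)).to_frame(),
    }

    rep_hist = repeat_category_histogram(kept)
    cgi = cgi_conservation_summary(cpg_islands, kept, annotation, seqs)
    l1 = l1_summary(repeats, kept, annotation) if repeats else pd.DataFrame(
        columns=["group", "median_l1_coverage", "n_l1", "frac_l1_conserved",
                 "frac_l1m"])
    promoters = {
        gid: promoter_of(g, chrom_lengths[g.chrom]) for gid, g in genes.items()
    }
    sites = gene_site_association(annotation, tfbs or {}, promoters) \
        if tfbs else pd.DataFrame(columns=["gene_id", "group"])

    return AnalysisResult(
        config=cfg,
        gene_features=gene_features,
        table1=table1,
        element_table=element_df,
        table2=table2,
        table3=table3,
        motif_results=motif_results,
        retention_fraction=retention,
        profiles=profiles,
        repeat_histogram=rep_hist,
        cgi_summary=cgi,
        l1_table=l1,
        site_table=sites,
        elements=kept,
        annotation=annotation,
    )


def run_analysis_on_bundle(bundle, config: AnalysisConfig | None = None) -> AnalysisResult:
    """Convenience wrapper for a synthetic :class:`GenomeBundle`."""
    import copy

    elements = [ConservedElement(e.chrom, e.start, e.end, e.score)
                for e in bundle.elements]
    return run_analysis(
        seqs=bundle.seqs,
        genes=bundle.genes,
        chrom_lengths=bundle.chrom_lengths,
        elements=elements,
        cpg_islands=bundle.cpg_islands,
        repeats=bundle.repeats,
        tfbs=bundle.tfbs,
        config=config,
    )


def load_inputs(
    fasta: str | Path,
    gtf: str | Path,
    elements_bed: str | Path,
    groups_tsv: str | Path | None = None,
    cpg_islands_bed: str | Path | None = None,
    repeats_bed: str | Path | None = None,
    tfbs_beds: Mapping[str, str | Path] | None = None,
):
    """Read flat-file inputs into the structures ``run_analysis`` expects."""
    from .genome_model import build_gene_models

    seqs = io_mod.read_fasta(fasta)
    chrom_lengths = {c: len(s) for c, s in seqs.items()}
    groups = io_mod.read_gene_groups(groups_tsv) if groups_tsv else {}
    genes = build_gene_models(io_mod.read_gtf(gtf), groups)
    elements = io_mod.read_elements_bed(elements_bed)
    islands = io_mod.read_bed3(cpg_islands_bed) if cpg_islands_bed else []
    repeats = io_mod.read_repeats_bed(repeats_bed) if repeats_bed else []
    tfbs = {name: io_mod.read_bed3(p) for name, p in (tfbs_beds or {}).items()}
    return dict(seqs=seqs, genes=genes, chrom_lengths=chrom_lengths,
                elements=elements, cpg_islands=islands, repeats=repeats,
                tfbs=tfbs)
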
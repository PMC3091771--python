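"""Synthetic genomes with planted group effects.

Generates complete, internally consistent toy genomes — sequence plus gene
annotation, conserved elements, CpG islands, repeats, TF-binding sites and a
gene-group file — so that every pipeline stage has ground truth.  The default
configuration plants the contrasts the pipeline is designed to detect:
imprinted (maternal/paternal) genes get roughly doubled intergenic regions,
reduced CpG deamination outside CpG islands (and slightly elevated
deamination inside them), a higher density of intronic conserved elements for
the paternal group, enriched intronic CpG islands, an older (L1M-dominated)
LINE-1 complement, and a planted CpG-containing 6-mer in the intronic
elements of the labelled groups.

The sequence model is i.i.d. with region-specific dinucleotide adjustments
(CpG density raised inside islands, then deaminated per gene territory)
rather than a full Markov chain — sufficient for every statistic the
pipeline computes.  Conservation scores are drawn from per-class gamma
distributions; only within-run comparisons of scores are meaningful.
Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import intervals as iv
from . import seqstats
from .element_annotator import ConservedElement, RepeatFeature
from .genome_model import (
    GeneModel,
    TranscriptRecord,
    partition_intergenic,
    promoter_of,
)

GROUPS = ("maternal", "paternal", "autosomal")


def _per_group(maternal: float, paternal: float, autosomal: float) -> dict[str, float]:
    return {"maternal": maternal, "paternal": paternal, "autosomal": autosomal}


@dataclass
class SyntheticGenomeConfig:
    """Study conditions for one synthetic genome.

    Rates named ``*_per10kb`` are retained-element densities (elements of at
    least 20 bp per 10 kb of the region class); the generator additionally
    emits a ``short_element_fraction`` of sub-20 bp elements that the length
    filter is expected to remove.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_200_000
    n_genes: int = 200
    group_proportions: dict[str, float] = field(
        default_factory=lambda: _per_group(0.10, 0.10, 0.80))
    group_counts: dict[str, int] | None = None  # overrides proportions

    # gene structure
    intronless_prob: float = 0.06
    extra_exon_mean: float = 4.0           # exon count = 2 + Poisson(mean)
    exon_length_log_mean: float = math.log(140.0)
    exon_length_log_sd: float = 0.4
    intron_length_log_mean: float = math.log(700.0)
    intron_length_log_sd: float = 0.6
    intron_length_multiplier: dict[str, float] = field(
        default_factory=lambda: _per_group(1.07, 1.05, 1.0))
    utr_fraction: float = 0.25             # of first/last exon left noncoding

    # intergenic spacing (each gene contributes one lognormal half per flank)
    intergenic_half_log_mean: float = math.log(1500.0)
    intergenic_half_log_sd: float = 0.6
    intergenic_multiplier: dict[str, float] = field(
        default_factory=lambda: _per_group(1.9, 2.1, 1.0))

    # base composition and CpG islands
    base_gc: float = 0.42
    island_prob_intronic: dict[str, float] = field(
        default_factory=lambda: _per_group(0.30, 0.30, 0.085))
    island_prob_promoter: float = 0.4
    island_length_range: tuple[int, int] = (400, 1000)
    island_gc: float = 0.65
    island_cpg_density: float = 0.08

    # CpG deamination probability per group (germline methylation surrogate):
    # applied outside islands at the group rate, inside islands at the island
    # rate (hypermethylated islands / hypomethylated surroundings contrast)
    deamination: dict[str, float] = field(
        default_factory=lambda: _per_group(0.45, 0.40, 0.60))
    island_deamination: dict[str, float] = field(
        default_factory=lambda: _per_group(0.12, 0.12, 0.10))

    # conserved elements
    element_rate_intronic_per10kb: dict[str, float] = field(
        default_factory=lambda: _per_group(1.35, 2.04, 1.06))
    element_rate_intergenic_per10kb: dict[str, float] = field(
        default_factory=lambda: _per_group(1.41, 1.29, 2.17))
    element_rate_coding_per10kb: float = 20.0
    element_rate_island_per10kb: float = 8.0
    element_length_log_mean: float = math.log(40.0)
    element_length_log_sd: float = 0.35
    short_element_fraction: float = 1.0 / 3.0
    exon_decay_bp: dict[str, float] = field(
        default_factory=lambda: _per_group(500.0, 500.0, 500.0))
    score_shape: float = 6.0
    score_median: dict[str, float] = field(default_factory=lambda: {
        "coding": 500.0, "intronic": 325.0, "intergenic": 335.0, "island": 390.0,
    })

    # repeats
    with_repeats: bool = True
    repeat_coverage: float = 0.08          # of intron + intergenic DNA
    repeat_category_weights: dict[str, float] = field(default_factory=lambda: {
        "SINE_Alu": 0.30, "MIR": 0.10, "L1": 0.25, "L2": 0.08,
        "LTR": 0.12, "MER": 0.08, "low_complexity_simple": 0.05, "other": 0.02,
    })
    repeat_length_median: dict[str, float] = field(default_factory=lambda: {
        "SINE_Alu": 300.0, "MIR": 180.0, "L1": 900.0, "L2": 400.0,
        "LTR": 450.0, "MER": 250.0, "low_complexity_simple": 60.0, "other": 200.0,
    })
    l1m_fraction: dict[str, float] = field(
        default_factory=lambda: _per_group(0.81, 0.81, 0.76))
    l1_density_multiplier: dict[str, float] = field(
        default_factory=lambda: _per_group(1.3, 1.3, 1.0))

    # TF-binding sites (probability that a gene has >= 1 site per region)
    with_tfbs: bool = True
    tfbs_site_length: int = 19
    tfbs_prob: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {
            "ctcf": {
                "intronic": _per_group(0.345, 0.345, 0.217),
                "intergenic": _per_group(0.293, 0.293, 0.264),
                "promoter": _per_group(0.10, 0.10, 0.10),
            },
            "yy1": {
                "intronic": _per_group(0.276, 0.276, 0.187),
                "intergenic": _per_group(0.345, 0.345, 0.236),
                "promoter": _per_group(0.10, 0.10, 0.10),
            },
        })

    # planted k-mer motif in the target groups' elements of one class
    planted_kmer: str | None = "GTCGCG"
    planted_fold: float = 5.0
    planted_target_groups: tuple[str, ...] = ("maternal", "paternal")
    planted_target_class: str = "intronic"

    def validate(self) -> None:
        for name, val in (
            ("intronless_prob", self.intronless_prob),
            ("base_gc", self.base_gc),
            ("island_gc", self.island_gc),
            ("island_cpg_density", self.island_cpg_density),
            ("short_element_fraction", self.short_element_fraction),
            ("repeat_coverage", self.repeat_coverage),
        ):
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0,1], got {val}")
        for grp in GROUPS:
            for d in (self.deamination[grp], self.island_deamination[grp]):
                if not 0 <= d <= 1:
                    raise ValueError(f"deamination probability {d} outside [0,1]")
        if self.planted_kmer is not None and not set(self.planted_kmer.upper()) <= set("ACGT"):
            raise ValueError(f"planted_kmer must be A/C/G/T, got {self.planted_kmer!r}")


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream verification."""

    groups: dict[str, str]                       # gene -> group
    element_classes: list[str]                   # parallel to bundle.elements
    element_genes: list[str]                     # parallel to bundle.elements
    deamination: dict[str, float]
    island_deamination: dict[str, float]
    planted_kmer: str | None
    planted_fold: float
    n_short_elements: int
    intronless_genes: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class GenomeBundle:
    """In-memory genome bundle: sequence, annotation tracks, ground truth."""

    config: SyntheticGenomeConfig
    chrom_lengths: dict[str, int]
    seqs: dict[str, str]
    transcripts: list[TranscriptRecord]
    genes: dict[str, GeneModel]
    elements: list[ConservedElement]             # raw, pre-filter
    cpg_islands: list[tuple[str, int, int]]
    repeats: list[RepeatFeature]
    tfbs: dict[str, list[tuple[str, int, int]]]
    ground_truth: GroundTruth

    @property
    def groups(self) -> dict[str, str]:
        return self.ground_truth.groups

    def write(self, outdir: str | Path) -> None:
        from . import io as io_mod

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io_mod.write_fasta(outdir / "genome.fa", self.seqs)
        io_mod.write_gtf(outdir / "genes.gtf", self.transcripts)
        io_mod.write_elements_bed(outdir / "conserved_elements.bed", self.elements)
        io_mod.write_bed3(outdir / "cpg_islands.bed", self.cpg_islands)
        io_mod.write_repeats_bed(outdir / "repeats.bed", self.repeats)
        for name, sites in self.tfbs.items():
            io_mod.write_bed3(outdir / f"tfbs_{name}.bed", sites)
        io_mod.write_gene_groups(outdir / "gene_groups.tsv", self.groups)
        (outdir / "ground_truth.json").write_text(self.ground_truth.to_json())


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _lognormal_int(rng, log_mean: float, log_sd: float, minimum: int = 1) -> int:
    return max(minimum, int(round(rng.lognormal(log_mean, log_sd))))


def _gene_structure(rng, cfg: SyntheticGenomeConfig, group: str):
    """Relative exon layout + CDS span for one gene. Returns (exons, cds)."""
    if rng.random() < cfg.intronless_prob:
        length = _lognormal_int(rng, math.log(1000.0), 0.4, minimum=300)
        exons = [(0, length)]
    else:
        n_exons = 2 + rng.poisson(cfg.extra_exon_mean)
        exons = []
        pos = 0
        mult = cfg.intron_length_multiplier[group]
        for i in range(n_exons):
            if i > 0:
                pos += max(50, int(round(
                    rng.lognormal(cfg.intron_length_log_mean, cfg.intron_length_log_sd) * mult)))
            ln = _lognormal_int(rng, cfg.exon_length_log_mean, cfg.exon_length_log_sd,
                                minimum=30)
            exons.append((pos, pos + ln))
            pos += ln
    first_len = exons[0][1] - exons[0][0]
    last_len = exons[-1][1] - exons[-1][0]
    cds_start = exons[0][0] + max(1, int(first_len * cfg.utr_fraction))
    cds_end = exons[-1][1] - max(1, int(last_len * cfg.utr_fraction))
    if cds_end <= cds_start:  # tiny single-exon gene: keep a 10 bp CDS core
        mid = (exons[0][0] + exons[-1][1]) // 2
        cds_start, cds_end = mid - 5, mid + 5
    return exons, (cds_start, cds_end)


def _score(rng, cfg: SyntheticGenomeConfig, cls: str) -> float:
    # gamma(k) has median ~ k - 1/3 scale units
    scale = cfg.score_median[cls] / (cfg.score_shape - 1.0 / 3.0)
    return float(rng.gamma(cfg.score_shape, scale))


def _element_length(rng, cfg: SyntheticGenomeConfig, short: bool) -> int:
    if short:
        return int(rng.integers(5, 20))
    return max(20, _lognormal_int(rng, cfg.element_length_log_mean,
                                  cfg.element_length_log_sd))


def generate(config: SyntheticGenomeConfig) -> GenomeBundle:
    """Generate a full genome bundle with the configured planted effects.

    Raises ``ValueError`` when the gene complement cannot be packed into
    ``n_chromosomes * chrom_length``.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- group labels -----------------------------------------------------
    if cfg.group_counts is not None:
        counts = dict(cfg.group_counts)
        if sum(counts.values()) != cfg.n_genes:
            raise ValueError("group_counts must sum to n_genes")
    else:
        counts = {g: int(round(cfg.group_proportions[g] * cfg.n_genes))
                  for g in ("maternal", "paternal")}
        counts["autosomal"] = cfg.n_genes - sum(counts.values())
    labels = [g for g in GROUPS for _ in range(counts.get(g, 0))]
    rng.shuffle(labels)

    # --- place genes ------------------------------------------------------
    per_chrom = np.array_split(np.arange(cfg.n_genes), cfg.n_chromosomes)
    transcripts: list[TranscriptRecord] = []
    genes: dict[str, GeneModel] = {}
    groups: dict[str, str] = {}
    chrom_lengths: dict[str, int] = {}
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    gidx = 0
    for ci, gene_idx in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = 0
        chrom_genes: list[GeneModel] = []
        for _ in gene_idx:
            gid = f"G{gidx:05d}"
            group = labels[gidx]
            gidx += 1
            mult = cfg.intergenic_multiplier[group]
            gap_in = max(200, int(round(
                rng.lognormal(cfg.intergenic_half_log_mean, cfg.intergenic_half_log_sd) * mult)))
            exons_rel, cds_rel = _gene_structure(rng, cfg, group)
            start = pos + gap_in
            exons = tuple((start + s, start + e) for s, e in exons_rel)
            cds = (start + cds_rel[0], start + cds_rel[1])
            strand = "+" if rng.random() < 0.5 else "-"
            tx = TranscriptRecord(gid, chrom, strand, exons[0][0], exons[-1][1],
                                  exons, cds[0], cds[1])
            transcripts.append(tx)
            if len(exons) >= 3 and rng.random() < 0.5:
                # a shorter splice variant; merging it back must reproduce
                # the full model
                sub = exons[1:]
                transcripts.append(TranscriptRecord(
                    gid, chrom, strand, sub[0][0], sub[-1][1], sub,
                    max(cds[0], sub[0][0]), cds[1]))
            model = GeneModel(gid, chrom, strand, exons[0][0], exons[-1][1],
                              list(exons), _cds_cover(exons, cds), group=group)
            genes[gid] = model
            groups[gid] = group
            chrom_genes.append(model)
            gap_out = max(200, int(round(
                rng.lognormal(cfg.intergenic_half_log_mean, cfg.intergenic_half_log_sd) * mult)))
            pos = model.end + gap_out
        if pos > cfg.chrom_length:
            raise ValueError(
                f"infeasible packing: {chrom} needs {pos} bp but chrom_length is "
                f"{cfg.chrom_length}; increase chrom_length or reduce n_genes")
        chrom_lengths[chrom] = cfg.chrom_length
        genes_by_chrom[chrom] = chrom_genes

    partitions = {
        chrom: partition_intergenic(gs, chrom_lengths[chrom])
        for chrom, gs in genes_by_chrom.items()
    }
    assigned: dict[str, list[tuple[str, int, int]]] = {}
    for chrom, regions in partitions.items():
        for r in regions:
            assigned.setdefault(r.assigned_gene_id, []).append((chrom, r.start, r.end))

    # --- base sequence ----------------------------------------------------
    p = np.array([(1 - cfg.base_gc) / 2, cfg.base_gc / 2,
                  cfg.base_gc / 2, (1 - cfg.base_gc) / 2])
    codes: dict[str, np.ndarray] = {
        chrom: rng.choice(4, size=n, p=p).astype(np.uint8)
        for chrom, n in chrom_lengths.items()
    }

    # --- CpG islands ------------------------------------------------------
    islands: list[tuple[str, int, int]] = []
    islands_by_gene: dict[str, list[tuple[str, int, int]]] = {}
    lo, hi = cfg.island_length_range
    for gid, gene in genes.items():
        placed = []
        if rng.random() < cfg.island_prob_intronic[gene.group]:
            introns = [i for i in gene.introns if i[1] - i[0] >= hi + 100]
            if introns:
                s0, e0 = introns[rng.integers(len(introns))]
                ln = int(rng.integers(lo, hi + 1))
                s = int(rng.integers(s0 + 20, e0 - ln - 20))
                placed.append((gene.chrom, s, s + ln))
        if rng.random() < cfg.island_prob_promoter:
            prom = promoter_of(gene, chrom_lengths[gene.chrom])
            ln = int(rng.integers(lo, hi + 1))
            if prom.end - prom.start >= ln:
                s = int(rng.integers(prom.start, prom.end - ln + 1))
                placed.append((gene.chrom, s, s + ln))
        for chrom, s, e in placed:
            codes[chrom][s:e] = seqstats.generate_cpg_sequence(
                e - s, cfg.island_cpg_density, rng, gc=cfg.island_gc)
        islands.extend(placed)
        islands_by_gene[gid] = placed

    island_ivs_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in islands:
        island_ivs_by_chrom.setdefault(chrom, []).append((s, e))
    for chrom in island_ivs_by_chrom:
        island_ivs_by_chrom[chrom] = iv.union(island_ivs_by_chrom[chrom])

    # --- deamination per gene territory ------------------------------------
    for gid, gene in genes.items():
        d = cfg.deamination[gene.group]
        d_isl = cfg.island_deamination[gene.group]
        territory = [(gene.chrom, gene.start, gene.end)] + assigned.get(gid, [])
        isl = islands_by_gene.get(gid, [])
        isl_ivs = iv.union([(s, e) for _, s, e in isl])
        for chrom, s, e in territory:
            for ps, pe in iv.subtract((s, e), isl_ivs):
                codes[chrom][ps:pe] = seqstats.deaminate(codes[chrom][ps:pe], d, rng)
        for chrom, s, e in isl:
            codes[chrom][s:e] = seqstats.deaminate(codes[chrom][s:e], d_isl, rng)

    # --- conserved elements -------------------------------------------------
    elements: list[ConservedElement] = []
    truth_class: list[str] = []
    truth_gene: list[str] = []
    n_short = 0
    # conserved-element tracks are disjoint by construction; mirror that by
    # rejecting placements that overlap an already placed element
    occupied: dict[str, list[tuple[int, int]]] = {}

    def emit(chrom: str, s: int, e: int, cls: str, score_cls: str,
             gid: str, short: bool) -> bool:
        nonlocal n_short
        s, e = int(s), int(e)
        occ = occupied.setdefault(chrom, [])
        if any(s < oe and e > os_ for os_, oe in occ):
            return False
        occ.append((s, e))
        elements.append(ConservedElement(chrom, s, e,
                                         round(_score(rng, cfg, score_cls), 1)))
        truth_class.append(cls)
        truth_gene.append(gid)
        if short:
            n_short += 1
        return True

    keep = 1.0 - cfg.short_element_fraction
    for gid, gene in genes.items():
        occupied = {}  # elements of different genes live in disjoint regions
        chrom = gene.chrom
        group = gene.group
        # intronic elements with exon-proximity decay
        introns = gene.introns
        intron_len = iv.total_length(introns)
        if introns and intron_len:
            n = rng.poisson(cfg.element_rate_intronic_per10kb[group]
                            * intron_len / 1e4 / keep)
            w = np.array([i[1] - i[0] for i in introns], dtype=float)
            w /= w.sum()
            for _ in range(n):
                short = rng.random() < cfg.short_element_fraction
                ln = _element_length(rng, cfg, short)
                for _try in range(8):
                    s0, e0 = introns[rng.choice(len(introns), p=w)]
                    if e0 - s0 <= ln + 2:
                        continue
                    dist = int(rng.exponential(cfg.exon_decay_bp[group]))
                    if rng.random() < 0.5:
                        s = s0 + 1 + dist      # measured from the left boundary
                    else:
                        s = e0 - 1 - dist - ln  # from the right boundary
                    s = min(max(s, s0 + 1), e0 - ln - 1)
                    if emit(chrom, s, s + ln, "intronic", "intronic", gid, short):
                        break
        # intergenic elements, uniform within the assigned halves
        for rchrom, rs, re_ in assigned.get(gid, []):
            rlen = re_ - rs
            n = rng.poisson(cfg.element_rate_intergenic_per10kb[group]
                            * rlen / 1e4 / keep)
            for _ in range(n):
                short = rng.random() < cfg.short_element_fraction
                ln = _element_length(rng, cfg, short)
                if rlen <= ln + 2:
                    continue
                for _try in range(8):
                    s = int(rng.integers(rs + 1, re_ - ln - 1))
                    if emit(rchrom, s, s + ln, "intergenic", "intergenic",
                            gid, short):
                        break
        # coding elements: wholly inside a coding exon or straddling into
        # the intron (negative-distance material for the exon profile)
        coding = gene.merged_coding
        coding_len = iv.total_length(coding)
        if coding_len:
            n = rng.poisson(cfg.element_rate_coding_per10kb * coding_len / 1e4 / keep)
            wc = np.array([c[1] - c[0] for c in coding], dtype=float)
            wc /= wc.sum()
            for _ in range(n):
                short = rng.random() < cfg.short_element_fraction
                ln = _element_length(rng, cfg, short)
                for _try in range(8):
                    cs, ce = coding[rng.choice(len(coding), p=wc)]
                    if ce - cs <= ln + 2:
                        continue
                    if rng.random() < 0.5:
                        s = int(rng.integers(cs, ce - ln))
                    else:  # straddle the exon start into the intron/UTR
                        s = max(0, cs - int(rng.integers(1, max(2, ln // 2))))
                    if emit(chrom, s, s + ln, "coding", "coding", gid, short):
                        break
        # island-hosted elements
        for ichrom, is_, ie in islands_by_gene.get(gid, []):
            n = rng.poisson(cfg.element_rate_island_per10kb * (ie - is_) / 1e4 / keep)
            for _ in range(n):
                short = rng.random() < cfg.short_element_fraction
                ln = _element_length(rng, cfg, short)
                if ie - is_ <= ln + 2:
                    continue
                for _try in range(8):
                    s = int(rng.integers(is_, ie - ln))
                    cls = "intronic" \
                        if iv.overlap_with_set((s, s + ln), introns) == ln \
                        else "intergenic"
                    if emit(ichrom, s, s + ln, cls, "island", gid, short):
                        break

    # --- planted motif ------------------------------------------------------
    if cfg.planted_kmer:
        kmer = seqstats.encode(cfg.planted_kmer.upper())
        k = kmer.size
        targets = [
            (i, el) for i, el in enumerate(elements)
            if truth_class[i] == cfg.planted_target_class
            and groups[truth_gene[i]] in cfg.planted_target_groups
            and el.length >= k
        ]
        if targets:
            windows = sum(el.length - k + 1 for _, el in targets)
            n_plant = int(round((cfg.planted_fold - 1.0) * windows / 4 ** k))
            wts = np.array([el.length - k + 1 for _, el in targets], dtype=float)
            wts /= wts.sum()
            for _ in range(n_plant):
                _, el = targets[rng.choice(len(targets), p=wts)]
                s = int(rng.integers(el.start, el.end - k + 1))
                codes[el.chrom][s:s + k] = kmer

    # --- repeats ------------------------------------------------------------
    repeats: list[RepeatFeature] = []
    if cfg.with_repeats:
        cats = list(cfg.repeat_category_weights)
        base_w = np.array([cfg.repeat_category_weights[c] for c in cats], dtype=float)
        for gid, gene in genes.items():
            group = gene.group
            w = base_w.copy()
            w[cats.index("L1")] *= cfg.l1_density_multiplier[group]
            w /= w.sum()
            regions = [(gene.chrom, s, e) for s, e in gene.introns] \
                + assigned.get(gid, [])
            isl_ivs = iv.union([(s, e) for _, s, e in islands_by_gene.get(gid, [])])
            mean_len = float(np.dot(w, [cfg.repeat_length_median[c] for c in cats]))
            for rchrom, rs, re_ in regions:
                rlen = re_ - rs
                n = rng.poisson(cfg.repeat_coverage * rlen / mean_len)
                for _ in range(n):
                    cat = cats[rng.choice(len(cats), p=w)]
                    ln = _lognormal_int(rng, math.log(cfg.repeat_length_median[cat]),
                                        0.4, minimum=30)
                    ln = min(ln, rlen - 2)
                    if ln < 30:
                        continue
                    for _try in range(5):
                        s = int(rng.integers(rs, re_ - ln))
                        if iv.overlap_with_set((s, s + ln), isl_ivs) == 0:
                            repeats.append(RepeatFeature(
                                rchrom, s, s + ln,
                                _repeat_name(rng, cfg, cat, group)))
                            break

    # --- TF-binding sites ---------------------------------------------------
    tfbs: dict[str, list[tuple[str, int, int]]] = {}
    if cfg.with_tfbs:
        site_len = cfg.tfbs_site_length
        for track, by_region in cfg.tfbs_prob.items():
            sites: list[tuple[str, int, int]] = []
            for gid, gene in genes.items():
                group = gene.group
                region_map = {
                    "intronic": [(gene.chrom, s, e) for s, e in gene.introns],
                    "intergenic": assigned.get(gid, []),
                }
                prom = promoter_of(gene, chrom_lengths[gene.chrom])
                region_map["promoter"] = [(prom.chrom, prom.start, prom.end)]
                for region, prob_by_group in by_region.items():
                    if rng.random() >= prob_by_group[group]:
                        continue
                    candidates = [r for r in region_map[region]
                                  if r[2] - r[1] > site_len + 2]
                    if not candidates:
                        continue
                    rchrom, rs, re_ = candidates[rng.integers(len(candidates))]
                    s = int(rng.integers(rs, re_ - site_len))
                    sites.append((rchrom, s, s + site_len))
            tfbs[track] = sorted(sites)

    seq_strings = {chrom: seqstats.decode(arr) for chrom, arr in codes.items()}
    truth = GroundTruth(
        groups=groups,
        element_classes=truth_class,
        element_genes=truth_gene,
        deamination=dict(cfg.deamination),
        island_deamination=dict(cfg.island_deamination),
        planted_kmer=cfg.planted_kmer,
        planted_fold=cfg.planted_fold,
        n_short_elements=n_short,
        intronless_genes=sorted(g.gene_id for g in genes.values() if g.is_intronless),
    )
    return GenomeBundle(
        config=cfg,
        chrom_lengths=chrom_lengths,
        seqs=seq_strings,
        transcripts=transcripts,
        genes=genes,
        elements=elements,
        cpg_islands=sorted(islands),
        repeats=sorted(repeats, key=lambda r: (r.chrom, r.start, r.end)),
        tfbs=tfbs,
        ground_truth=truth,
    )


def _cds_cover(exons: Sequence[tuple[int, int]], cds: tuple[int, int]):
    out = []
    for s, e in exons:
        c = iv.clip((s, e), cds[0], cds[1])
        if c:
            out.append(c)
    return out


_L1M_FAMILIES = ("L1MA4", "L1MB7", "L1MC3", "L1MD2", "L1ME1")
_L1P_FAMILIES = ("L1PA3", "L1PA7", "L1PB1", "L1PREC2", "L1HS")
_NAMES = {
    "SINE_Alu": ("AluY", "AluSx", "AluJb"),
    "MIR": ("MIR", "MIRb", "MIR3"),
    "L2": ("L2a", "L2b", "L2c"),
    "LTR": ("MLT1A", "MSTB", "ERVL-B4", "LTR16A"),
    "MER": ("MER5A", "MER20", "MER41B"),
    "low_complexity_simple": ("(TG)n", "(CA)n", "GC_rich", "A-rich"),
    "other": ("Charlie1", "Tigger3"),
}


def _repeat_name(rng, cfg: SyntheticGenomeConfig, cat: str, group: str) -> str:
    if cat == "L1":
        fams = _L1M_FAMILIES if rng.random() < cfg.l1m_fraction[group] \
            else _L1P_FAMILIES
        return fams[rng.integers(len(fams))]
    pool = _NAMES[cat]
    return pool[rng.integers(len(pool))]


def null_config(seed: int = 0, **overrides) -> SyntheticGenomeConfig:
    """A structureless configuration: identical group distributions, no
    planted motif — every downstream contrast should be null."""
    cfg = SyntheticGenomeConfig(
        seed=seed,
        intergenic_multiplier=_per_group(1.0, 1.0, 1.0),
        intron_length_multiplier=_per_group(1.0, 1.0, 1.0),
        deamination=_per_group(0.5, 0.5, 0.5),
        island_deamination=_per_group(0.1, 0.1, 0.1),
        island_prob_intronic=_per_group(0.15, 0.15, 0.15),
        element_rate_intronic_per10kb=_per_group(1.5, 1.5, 1.5),
        element_rate_intergenic_per10kb=_per_group(1.8, 1.8, 1.8),
        l1m_fraction=_per_group(0.78, 0.78, 0.78),
        l1_density_multiplier=_per_group(1.0, 1.0, 1.0),
        planted_kmer=None,
        tfbs_prob={
            "ctcf": {r: _per_group(0.25, 0.25, 0.25)
                     for r in ("intronic", "intergenic", "promoter")},
            "yy1": {r: _per_group(0.22, 0.22, 0.22)
                    for r in ("intronic", "intergenic", "promoter")},
        },
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def contrast_config(seed: int = 0, **overrides) -> SyntheticGenomeConfig:
    """Planted-contrast study conditions for the parameter-recovery checks.

    A 58-gene labelled set (29 maternal + 29 paternal) against 142 autosomal
    genes with gene bodies carrying realistic intron content (~12 kb per
    gene), planting three contrasts: doubled intergenic halves for the
    labelled groups, a CpG-deamination differential (d = 0.4 labelled vs 0.6
    autosomal), and a threefold elevation of intronic conserved-element
    density for the paternal group.  Repeats, TF-binding sites and the motif
    plant are disabled — they are irrelevant to these contrasts.
    """
    cfg = SyntheticGenomeConfig(
        seed=seed,
        n_chromosomes=1,
        chrom_length=4_800_000,
        n_genes=200,
        group_counts={"maternal": 29, "paternal": 29, "autosomal": 142},
        extra_exon_mean=6.0,
        intron_length_log_mean=math.log(1500.0),
        intron_length_multiplier=_per_group(1.0, 1.0, 1.0),
        intergenic_multiplier=_per_group(2.0, 2.0, 1.0),
        deamination=_per_group(0.4, 0.4, 0.6),
        element_rate_intronic_per10kb=_per_group(1.06, 3.18, 1.06),
        element_rate_intergenic_per10kb=_per_group(1.8, 1.8, 1.8),
        island_prob_intronic=_per_group(0.15, 0.15, 0.15),
        with_repeats=False,
        with_tfbs=False,
        planted_kmer=None,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def motif_study_config(
    seed: int = 0,
    fold: float = 5.0,
    kmer: str | None = "GTCGCG",
    **overrides,
) -> SyntheticGenomeConfig:
    """Motif-recovery study conditions: one labelled group of 30 genes with
    intron-dense bodies and a high intronic element rate, yielding ~60 kb of
    target element sequence, against an equally sized autosomal comparison
    and the ~1.2 Mb genome as background."""
    cfg = SyntheticGenomeConfig(
        seed=seed,
        n_chromosomes=1,
        chrom_length=1_500_000,
        n_genes=60,
        group_counts={"maternal": 30, "paternal": 0, "autosomal": 30},
        extra_exon_mean=6.0,
        intron_length_log_mean=math.log(1500.0),
        intron_length_multiplier=_per_group(1.0, 1.0, 1.0),
        intergenic_multiplier=_per_group(1.0, 1.0, 1.0),
        deamination=_per_group(0.5, 0.5, 0.5),
        element_rate_intronic_per10kb=_per_group(40.0, 40.0, 40.0),
        element_rate_intergenic_per10kb=_per_group(1.0, 1.0, 1.0),
        island_prob_intronic=_per_group(0.0, 0.0, 0.0),
        island_prob_promoter=0.0,
        short_element_fraction=0.0,
        with_repeats=False,
        with_tfbs=False,
        planted_kmer=kmer,
        planted_fold=fold,
        planted_target_groups=("maternal",),
        planted_target_class="intronic",
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


STUDY_SHAPED_SEED = 649


def study_shaped_fixture(seed: int = STUDY_SHAPED_SEED) -> GenomeBundle:
    """Deterministic regression fixture shaped like the study design:
    58 labelled genes (28 maternal + 30 paternal) against a 1000-gene
    autosomal background, with all default planted contrasts."""
    cfg = SyntheticGenomeConfig(
        seed=seed,
        n_chromosomes=4,
        chrom_length=3_000_000,
        n_genes=1058,
        group_counts={"maternal": 28, "paternal": 30, "autosomal": 1000},
    )
    return generate(cfg)
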
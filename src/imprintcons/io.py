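"""Readers and writers for the flat-file formats the pipeline consumes.

Coordinates are 0-based half-open in memory (BED convention); GTF input is
converted on read and back on write.  Readers accept flat-file exports only
(no live database access).
"""

from __future__ import annotations

import textwrap
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .element_annotator import ConservedElement, RepeatFeature
from .genome_model import GeneModel, IntergenicRegion, TranscriptRecord


# --- FASTA -----------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Chromosome name -> sequence, via pyfaidx random access."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            for line in textwrap.wrap(seqs[name], width,
                                      break_on_hyphens=False):
                fh.write(line + "\n")


# --- GTF / BED12 gene annotation -------------------------------------------

def read_gtf(path: str | Path) -> list[TranscriptRecord]:
    """Parse exon and CDS features into transcript records.

    Requires ``gene_id`` and ``transcript_id`` attributes; 1-based inclusive
    GTF coordinates are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_id = feat.attributes["transcript_id"][0]
        rec = by_tx.setdefault(tx_id, {
            "gene_id": feat.attributes["gene_id"][0],
            "chrom": feat.seqid, "strand": feat.strand,
            "exons": [], "cds": [],
        })
        interval = (feat.start - 1, feat.end)  # to half-open
        rec["exons" if feat.featuretype == "exon" else "cds"].append(interval)
    records = []
    for tx in by_tx.values():
        exons = tuple(sorted(tx["exons"]))
        cds = sorted(tx["cds"])
        records.append(TranscriptRecord(
            gene_id=tx["gene_id"], chrom=tx["chrom"], strand=tx["strand"],
            tx_start=exons[0][0], tx_end=exons[-1][1], exons=exons,
            cds_start=cds[0][0] if cds else None,
            cds_end=cds[-1][1] if cds else None,
        ))
    return records


def write_gtf(path: str | Path, transcripts: Sequence[TranscriptRecord]) -> None:
    with open(path, "w") as fh:
        tx_counter: dict[str, int] = {}
        for t in transcripts:
            n = tx_counter.get(t.gene_id, 0) + 1
            tx_counter[t.gene_id] = n
            tx_id = f"{t.gene_id}.{n}"
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{tx_id}";'
            for s, e in t.exons:
                fh.write(f"{t.chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t"
                         f"{t.strand}\t.\t{attrs}\n")
            if t.cds_start is not None:
                for s, e in t.coding_intervals:
                    fh.write(f"{t.chrom}\tsynthetic\tCDS\t{s + 1}\t{e}\t.\t"
                             f"{t.strand}\t0\t{attrs}\n")


def read_bed12(path: str | Path) -> list[TranscriptRecord]:
    """BED12 transcript models; name column = gene id, thick = CDS span."""
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + sz)
                          for o, sz in zip(starts, sizes))
            has_cds = thick_e > thick_s
            records.append(TranscriptRecord(
                gene_id=name, chrom=chrom, strand=strand,
                tx_start=start, tx_end=end, exons=exons,
                cds_start=thick_s if has_cds else None,
                cds_end=thick_e if has_cds else None,
            ))
    return records


def write_models_bed6(path: str | Path, genes: Iterable[GeneModel]) -> None:
    """Merged gene models as BED6 (name = gene id, score 0)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_intergenic_bed6(path: str | Path,
                          regions: Iterable[IntergenicRegion]) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t"
                     f"{r.assigned_gene_id or '.'}\t0\t.\n")


# --- scored elements and simple tracks --------------------------------------

def read_elements_bed(path: str | Path) -> list[ConservedElement]:
    """BED5/BED6 conserved elements; column 5 is the conservation score."""
    els = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            els.append(ConservedElement(f[0], int(f[1]), int(f[2]), score))
    return els


def write_elements_bed(path: str | Path,
                       elements: Sequence[ConservedElement]) -> None:
    with open(path, "w") as fh:
        for i, el in enumerate(elements):
            fh.write(f"{el.chrom}\t{el.start}\t{el.end}\tpcs_{i}\t{el.score:g}\n")


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bed3(path: str | Path,
               intervals: Sequence[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


# --- repeats -----------------------------------------------------------------

def read_repeats_bed(path: str | Path) -> list[RepeatFeature]:
    """BED with the repeat family name in column 4 (and class in column 7
    when present)."""
    reps = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            rep_class = f[6] if len(f) > 6 else ""
            reps.append(RepeatFeature(f[0], int(f[1]), int(f[2]), f[3], rep_class))
    return reps


def write_repeats_bed(path: str | Path, repeats: Sequence[RepeatFeature]) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t.\t{r.rep_class}\n")


def read_repeatmasker_out(path: str | Path) -> list[RepeatFeature]:
    """RepeatMasker .out table (whitespace-delimited, 3 header lines).

    Coordinates in .out files are 1-based inclusive and converted here.
    """
    reps = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            fields = line.split()
            if not fields or not fields[0].isdigit():
                continue  # header/blank lines
            chrom, start, end = fields[4], int(fields[5]) - 1, int(fields[6])
            name, rep_class = fields[9], fields[10]
            reps.append(RepeatFeature(chrom, start, end, name, rep_class))
    return reps


# --- gene groups and stats tables --------------------------------------------

def read_gene_groups(path: str | Path) -> dict[str, str]:
    """Two-column TSV: gene_id, group label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "group"],
                     comment="#", dtype=str)
    return dict(zip(df["gene_id"], df["group"]))


def write_gene_groups(path: str | Path, groups: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for gid in sorted(groups):
            fh.write(f"{gid}\t{groups[gid]}\n")


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    """Deterministic TSV dump (fixed float format, no index)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
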
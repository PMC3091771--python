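"""k-mer enrichment of a target sequence collection against a genomic
background and a comparison collection.

Element sequences are concatenated per gene with six-``N`` separators so that
no artificial k-mer spans two elements.  Counting is single-strand (motifs
are reported oriented) over overlapping windows; windows containing ``N`` are
skipped.  Enrichment is a binomial z-score

    z = (observed - expected) / sqrt(expected * (1 - p_hat)),

with ``p_hat`` the k-mer's window frequency in the reference and
``expected = p_hat * windows_target``.  A motif passes when its score against
the genomic background AND against the comparison collection both reach the
threshold (default 3.5).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import seqstats

SEPARATOR = "N" * 6
DEFAULT_K = 6
DEFAULT_THRESHOLD = 3.5


@dataclass(frozen=True)
class MotifResult:
    kmer: str
    count_target: int
    count_background: int
    count_comparison: int
    score_vs_genome: float
    score_vs_comparison: float
    threshold: float = DEFAULT_THRESHOLD

    @property
    def contains_cpg(self) -> bool:
        return "CG" in self.kmer

    @property
    def passes(self) -> bool:
        return (self.score_vs_genome >= self.threshold
                and self.score_vs_comparison >= self.threshold)

    @property
    def min_score(self) -> float:
        return min(self.score_vs_genome, self.score_vs_comparison)


def mask_sequence(seq: str, mask_intervals: Iterable[tuple[int, int]]) -> str:
    """Replace the given (sequence-local, half-open) intervals with ``N``."""
    chars = list(seq)
    for s, e in mask_intervals:
        for i in range(max(0, s), min(len(chars), e)):
            chars[i] = "N"
    return "".join(chars)


def concatenate_by_gene(
    seqs_by_gene: Mapping[str, Sequence[str]], separator: str = SEPARATOR
) -> dict[str, str]:
    """Join each gene's element sequences with N-block separators."""
    return {g: separator.join(seqs) for g, seqs in seqs_by_gene.items()}


def kmer_index(kmer: str) -> int:
    idx = 0
    for c in kmer.upper():
        idx = idx * 4 + "ACGT".index(c)
    return idx


def kmer_from_index(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def kmer_count_array(seqs: str | Iterable[str], k: int = DEFAULT_K) -> tuple[np.ndarray, int]:
    """Counts over all 4^k k-mers plus the number of valid windows.

    Windows containing an ``N`` are skipped; counting is strand-as-given.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if isinstance(seqs, str):
        seqs = [seqs]
    counts = np.zeros(4 ** k, dtype=np.int64)
    for seq in seqs:
        codes = seqstats.encode(seq).astype(np.int64)
        n = codes.size
        if n < k:
            continue
        # rolling base-4 encoding; windows with any N invalidated
        valid = codes < 4
        safe = np.where(valid, codes, 0)
        idx = np.zeros(n - k + 1, dtype=np.int64)
        ok = np.ones(n - k + 1, dtype=bool)
        for j in range(k):
            idx = idx * 4 + safe[j:n - k + 1 + j]
            ok &= valid[j:n - k + 1 + j]
        counts += np.bincount(idx[ok], minlength=4 ** k)
    return counts, int(counts.sum())


def kmer_counts(seq: str | Iterable[str], k: int = DEFAULT_K) -> Counter:
    """Readable Counter of observed k-mers (zero-count k-mers omitted)."""
    arr, _ = kmer_count_array(seq, k)
    nz = np.nonzero(arr)[0]
    return Counter({kmer_from_index(int(i), k): int(arr[i]) for i in nz})


def enrichment_score(
    count_target: int,
    windows_target: int,
    count_ref: int,
    windows_ref: int,
    pseudocount: float = 0.0,
) -> float:
    """Binomial z-score of the target count against the reference frequency.

    With ``pseudocount == 0`` and a reference frequency of zero the score is
    ``inf`` for a nonzero observation (flagged-infinite case); pass a
    pseudocount to regularise zero-frequency k-mers.
    """
    if windows_target <= 0 or windows_ref <= 0:
        raise ValueError("window counts must be positive")
    p_hat = (count_ref + pseudocount) / (windows_ref + pseudocount)
    expected = p_hat * windows_target
    if expected == 0:
        return math.inf if count_target > 0 else 0.0
    return (count_target - expected) / math.sqrt(expected * (1 - p_hat))


def _score_vector(
    counts_t: np.ndarray, windows_t: int,
    counts_r: np.ndarray, windows_r: int,
    pseudocount: float,
) -> np.ndarray:
    p_hat = (counts_r + pseudocount) / (windows_r + pseudocount)
    expected = p_hat * windows_t
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (counts_t - expected) / np.sqrt(expected * (1 - p_hat))
    z = np.where(expected == 0, np.where(counts_t > 0, np.inf, 0.0), z)
    return z


def enriched_motifs(
    target: Iterable[str],
    background: Iterable[str],
    comparison: Iterable[str],
    k: int = DEFAULT_K,
    threshold: float = DEFAULT_THRESHOLD,
    pseudocount: float = 0.0,
    return_all: bool = False,
) -> list[MotifResult]:
    """k-mers over-represented versus both the background and the comparison.

    Returns motifs whose two scores both reach ``threshold``, sorted by the
    smaller of the two scores, descending (ties by k-mer); with
    ``return_all`` every k-mer is returned unsorted-filtered for inspection.
    """
    ct, wt = kmer_count_array(target, k)
    cb, wb = kmer_count_array(background, k)
    cc, wc = kmer_count_array(comparison, k)
    if wt == 0 or wb == 0 or wc == 0:
        raise ValueError("empty target/background/comparison collection")
    z_genome = _score_vector(ct, wt, cb, wb, pseudocount)
    z_comp = _score_vector(ct, wt, cc, wc, pseudocount)
    results = []
    for i in range(4 ** k):
        if not return_all and not (
            z_genome[i] >= threshold and z_comp[i] >= threshold
        ):
            continue
        results.append(MotifResult(
            kmer=kmer_from_index(i, k),
            count_target=int(ct[i]),
            count_background=int(cb[i]),
            count_comparison=int(cc[i]),
            score_vs_genome=float(z_genome[i]),
            score_vs_comparison=float(z_comp[i]),
            threshold=threshold,
        ))
    results.sort(key=lambda m: (-m.min_score, m.kmer))
    return results


def shared_motifs(
    run_a: Sequence[MotifResult], run_b: Sequence[MotifResult]
) -> list[str]:
    """k-mers passing in both runs (the two-species intersection logic)."""
    a = {m.kmer for m in run_a if m.passes}
    b = {m.kmer for m in run_b if m.passes}
    return sorted(a & b)
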
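"""Sequence-composition statistics: G+C, CpG_obs/CpG_exp, deamination index.

The deamination index (TpG+CpA)/(2*CpG) tracks the decay of methylated CpG
dinucleotides: 5-methylcytosine deaminates to thymine, turning CpG into TpG on
one strand and CpA on the other.  High values indicate accumulated CpG decay
(historically methylated sequence), low values CpG maintenance.  The
CpG_obs/CpG_exp ratio follows the Gardiner-Garden convention
``n_CpG * L / (n_C * n_G)``.

Counting rules: dinucleotide windows are overlapping, single-strand, and any
window containing an ``N`` is skipped; when statistics are pooled over an
interval set no window spans an interval boundary (intervals are biologically
discontiguous).  Soft-masked (lowercase) sequence is uppercased by default, or
converted to ``N`` on request to mirror repeat masking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

_BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4

DINUCLEOTIDES = tuple(a + b for a in _BASES for b in _BASES)


@dataclass(frozen=True)
class CompositionStats:
    """Pooled composition of one sequence or interval set."""

    length_effective: int  # non-N bases counted
    n_C: int
    n_G: int
    n_CpG: int
    n_TpG: int
    n_CpA: int
    n_windows: int  # valid (N-free, non-boundary) dinucleotide windows

    @property
    def gc(self) -> float | None:
        if self.length_effective == 0:
            return None
        return (self.n_C + self.n_G) / self.length_effective

    @property
    def cpg_oe(self) -> float | None:
        """CpG_obs/CpG_exp; absent when the sequence has no C or no G."""
        if self.n_C * self.n_G == 0:
            return None
        return self.n_CpG * self.length_effective / (self.n_C * self.n_G)

    @property
    def deamination_index(self) -> float | None:
        """(TpG+CpA)/(2*CpG); absent when there is no CpG left to normalise by."""
        if self.n_CpG == 0:
            return None
        return (self.n_TpG + self.n_CpA) / (2 * self.n_CpG)

    @property
    def has_cpg(self) -> bool:
        return self.n_CpG >= 1

    @property
    def empty(self) -> bool:
        return self.length_effective == 0


def encode(seq: str, lowercase_to_n: bool = False) -> np.ndarray:
    """Map a nucleotide string to codes A=0 C=1 G=2 T=3 N=4.

    Raises ``ValueError`` naming the first offending position for characters
    outside ``{A,C,G,T,N}`` (case-insensitive).
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(f"non-IUPAC character {seq[pos]!r} at position {pos}")
    if lowercase_to_n:
        lower = (raw >= ord("a")) & (raw <= ord("z"))
        codes = codes.copy()
        codes[lower] = 4
    return codes


def dinucleotide_counts(
    seq: str | np.ndarray, lowercase_to_n: bool = False
) -> dict[str, int]:
    """Counts of all 16 dinucleotides in overlapping windows.

    Windows containing ``N`` are skipped; counting is strand-as-given (no
    reverse-complement folding).
    """
    codes = seq if isinstance(seq, np.ndarray) else encode(seq, lowercase_to_n)
    counts = _dinuc_array(codes)
    return {d: int(counts[i]) for i, d in enumerate(DINUCLEOTIDES)}


def _dinuc_array(codes: np.ndarray) -> np.ndarray:
    """16-vector of dinucleotide counts (row-major A..T x A..T)."""
    if codes.size < 2:
        return np.zeros(16, dtype=np.int64)
    a, b = codes[:-1], codes[1:]
    valid = (a < 4) & (b < 4)
    pair = a[valid].astype(np.int64) * 4 + b[valid]
    return np.bincount(pair, minlength=16)


def _stats_from_codes(codes: np.ndarray) -> CompositionStats:
    base_counts = np.bincount(codes[codes < 4], minlength=4)
    d = _dinuc_array(codes)
    return CompositionStats(
        length_effective=int(base_counts.sum()),
        n_C=int(base_counts[1]),
        n_G=int(base_counts[2]),
        n_CpG=int(d[1 * 4 + 2]),
        n_TpG=int(d[3 * 4 + 2]),
        n_CpA=int(d[1 * 4 + 0]),
        n_windows=int(d.sum()),
    )


def composition(seq: str | np.ndarray, lowercase_to_n: bool = False) -> CompositionStats:
    """Composition statistics of a single sequence.

    An empty or all-N sequence yields ``CompositionStats`` with
    ``length_effective == 0`` and all ratios absent (``empty`` flag set).
    """
    codes = seq if isinstance(seq, np.ndarray) else encode(seq, lowercase_to_n)
    return _stats_from_codes(codes)


def merge_stats(parts: Iterable[CompositionStats]) -> CompositionStats:
    """Pool counts over parts; no window crosses a part boundary."""
    le = nc = ng = ncpg = ntpg = ncpa = nw = 0
    for p in parts:
        le += p.length_effective
        nc += p.n_C
        ng += p.n_G
        ncpg += p.n_CpG
        ntpg += p.n_TpG
        ncpa += p.n_CpA
        nw += p.n_windows
    return CompositionStats(le, nc, ng, ncpg, ntpg, ncpa, nw)


def composition_of_intervals(
    intervals: Sequence[tuple[int, int]],
    seq: "str | np.ndarray | Mapping[str, str]",
    chrom: str | None = None,
    lowercase_to_n: bool = False,
) -> CompositionStats:
    """Pooled composition over an interval set on one chromosome.

    ``seq`` may be a string/array for the chromosome or a mapping of
    chromosome name to sequence (then ``chrom`` selects one; pyfaidx Fasta
    objects satisfy the mapping protocol via ``str()`` conversion).
    Dinucleotide windows never span interval boundaries.  Intervals outside
    the chromosome raise ``ValueError``.
    """
    if isinstance(seq, Mapping) or hasattr(seq, "keys"):
        if chrom is None:
            raise ValueError("chrom required when seq is a mapping")
        seq = str(seq[chrom])
    codes = seq if isinstance(seq, np.ndarray) else encode(seq, lowercase_to_n)
    n = codes.size
    parts = []
    for s, e in intervals:
        if s < 0 or e > n:
            raise ValueError(f"interval ({s},{e}) outside chromosome of length {n}")
        parts.append(_stats_from_codes(codes[s:e]))
    return merge_stats(parts)


# ---------------------------------------------------------------------------
# CpG deamination simulator — the validation oracle for the deamination index
# ---------------------------------------------------------------------------

def generate_cpg_sequence(
    length: int, cpg_density: float, rng: np.random.Generator, gc: float = 0.5
) -> np.ndarray:
    """i.i.d. background sequence with CpG dinucleotides planted at a target
    density (expected CpGs per base), returned as a code array."""
    if not 0 <= cpg_density <= 1:
        raise ValueError(f"cpg_density must be in [0,1], got {cpg_density}")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    n_cpg = int(round(cpg_density * length))
    if n_cpg and length >= 2:
        # non-overlapping CpG starts on an even grid keeps planting exact
        slots = np.arange(0, length - 1, 2)
        pick = rng.choice(slots.size, size=min(n_cpg, slots.size), replace=False)
        pos = slots[pick]
        codes[pos] = 1
        codes[pos + 1] = 2
    return codes


def deaminate(
    codes: np.ndarray, d: float, rng: np.random.Generator
) -> np.ndarray:
    """Convert each CpG to TpG or CpA (equal probability) with probability d.

    Models methylation-driven deamination of 5mC: C->T on the methylated
    strand appears as CpG->TpG, on the template strand as CpG->CpA.
    """
    if not 0 <= d <= 1:
        raise ValueError(f"deamination probability must be in [0,1], got {d}")
    out = codes.copy()
    if d == 0 or out.size < 2:
        return out
    is_cpg = (out[:-1] == 1) & (out[1:] == 2)
    pos = np.nonzero(is_cpg)[0]
    hit = pos[rng.random(pos.size) < d]
    to_tpg = rng.random(hit.size) < 0.5
    out[hit[to_tpg]] = 3        # CpG -> TpG
    out[hit[~to_tpg] + 1] = 0   # CpG -> CpA
    return out


def deamination_simulator(
    ancestral_cpg_density: float,
    deamination_prob: float,
    length: int,
    seed: int | np.random.Generator,
) -> str:
    """Generate an ancestral CpG-bearing sequence and apply deamination.

    Deterministic under ``seed``.  Returns the evolved sequence as a string.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ancestral = generate_cpg_sequence(length, ancestral_cpg_density, rng)
    evolved = deaminate(ancestral, deamination_prob, rng)
    return decode(evolved)


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")
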
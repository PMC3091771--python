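# Methods

This note documents the conventions, model assumptions, default parameters
and numerical choices behind the package. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and gene models

All coordinates are 0-based, half-open (BED convention); GTF input is
converted on read. A gene is the union of its transcripts: span = most 5'
TSS to most 3' TTS, exons and CDS intervals interval-unioned ("longest
possible transcript", "largest possible coding region"). Introns are the
span minus the merged exons, so exon + intron lengths tile the span exactly;
a gene is intronless iff the merged model has a single exon block.
Transcripts of one gene must share chromosome and strand; violations are
rejected rather than repaired.

**Intergenic halving.** The DNA between two consecutive gene spans is cut at
the midpoint and each half assigned to the nearer gene; terminal segments go
wholly to the nearest (first/last) gene. For an odd-length gap the extra
base goes to the lower-coordinate gene (midpoint `m = ceil((a+b)/2)`), which
is exactly the per-base nearest-gene rule with ties broken to the
lower-coordinate gene — the equivalence is asserted against a per-base
oracle in the tests. Overlapping gene spans produce an empty gap; no base is
assigned twice. The emitted partition plus the gene spans reconstructs the
chromosome exactly.

**Promoters** are the 1000 bp upstream of the most upstream TSS, strand
aware, clipped only at chromosome bounds — deliberately *not* clipped by
neighbouring genes, since the definition is positional.

## Composition statistics

For a sequence with base counts n(A..T) over non-N positions:

* `gc = (n_C + n_G) / length_effective`
* `cpg_oe = n_CpG · length_effective / (n_C · n_G)` — the Gardiner-Garden
  normalization, the same convention that underlies standard CpG-island
  tracks. Absent when the sequence lacks C or G.
* `deamination_index = (n_TpG + n_CpA) / (2 · n_CpG)` — absent when the
  sequence has no CpG. TpG and CpA are the two strands' products of
  methylated-CpG deamination; their sum is invariant under reverse
  complement (asserted as a property test), which is why the numerator pairs
  them.

Dinucleotide windows are overlapping and single-strand; windows containing N
are skipped, and when counts are pooled over an interval set no window spans
an interval boundary (pooled intervals are biologically discontiguous, e.g.
all introns of a gene). Soft-masked lowercase is uppercased by default; an
optional mode converts lowercase to N to mirror repeat masking. Whether
gene-level ratios should be computed masked or unmasked is left to the
caller; both modes are exposed.

The deamination simulator draws an i.i.d. background (default G+C 0.42),
plants non-overlapping CpGs at a target density, then converts each CpG with
probability d to TpG or CpA (equal odds). It is the validation oracle for
the index: the acceptance suite asserts Spearman rho = 1 between d and the
measured index over d ∈ {0.1..0.9} (20 seeds, 100 kb), and that cpg_oe is
correspondingly decreasing.

## Element classification

Raw conserved elements shorter than 20 bp are discarded first (the track
convention this emulates anchors elements to a reference genome, where very
short anchors are alignment artefacts). Classification of a retained
element:

1. If it overlaps ≥1 gene span, it belongs to the gene with the larger
   overlap (ties to the lower-coordinate gene) and is `coding` if ≥1 bp
   overlaps the merged coding cover, else `UTR` if ≥1 bp overlaps a merged
   exon, else `intronic`. An element straddling the span edge follows this
   genic rule — never double-counted as intergenic.
2. Otherwise it is `intergenic`, assigned to the gene owning the containing
   intergenic half (larger overlap on a midpoint straddle, ties to the
   lower-coordinate region). On a chromosome without genes the assignment is
   absent and flagged.

`fully_coding` means the element interval is contained in the coding cover.
Feature overlap (CpG island, repeat, TF site) requires ≥ 1 bp; half-open
adjacency does not count. `unique` elements have no exon overlap, no repeat
flag, and no island flag. Repeat categories derive from family names
(Alu* → SINE_Alu, MIR* → MIR, L1* → L1, L2* → L2, LTR/MLT/MST/ERV/THE → LTR,
MER* → MER, low-complexity/simple classes, otherwise "other"); names
beginning `L1M` form the ancient mammalian-wide L1 subgroup. The
first-overlapping-repeat category is the overlapping repeat with the
smallest start (ties: longer overlap, then name).

**Exon distances.** For the distance profile, a purely intronic element's
distance is the minimal gap from either element edge to the nearest exon
boundary of its host gene (0 when abutting); an exon-overlapping element
gets a negative distance equal to its penetration depth measured from the
nearest overlapped boundary into the exon, and an element fully inside an
exon uses minus the minimal gap to either exon boundary. Equidistant
boundaries need no tie-break under this nearest-edge convention. Profile
bins are 100 bp; counts are normalized by the intron count of the profiled
gene group, and elements beyond 10 kb are excluded.

**Per-gene normalization.** Coverage is covered bases / summed region length
per gene; density is element count · 10⁴ / summed region length ("per
10 kb"). Group summaries are medians over genes; genes with a zero-length
region class are excluded from that summary.

## Group comparisons

Distributions are compared with a two-sided Wilcoxon rank-sum
(Mann-Whitney) test: exact enumeration for tie-free samples of ≤ 20 per
group, otherwise the tie-corrected normal approximation with continuity
correction. Proportions use Pearson's χ² on the 2×2 table *without* Yates
correction, falling back to Fisher's exact test when any expected cell is
below 5 — the uncorrected χ² holds its nominal size at the sample sizes
where it is selected (verified at 10⁴ null simulations in the acceptance
suite), while the Yates-corrected version is conservative.

Raw p values are reported and interpreted on a fixed tier scale: p < 0.005
highly significant, 0.005 ≤ p < 0.01 moderately significant, 0.01 ≤ p < 0.05
a trend, otherwise ns. No further multiple-testing machinery is applied; the
0.005 threshold plays the role of a Bonferroni-safe level for a feature
battery of this size.

**Random-set calibration** re-runs a comparison for n random gene subsets
(default 100) of the labelled-set size (default 58) drawn without
replacement from the background pool, each compared against the remaining
pool (the sampled set is excluded from its own reference — the alternative
inclusion convention changes the reference negligibly for pools ≫ 58), and
reports the fraction reaching the observed tier. On a structureless pool
this fraction estimates the tier's nominal rate; for a genuinely planted
labelled-set effect it is near 0.

## Motif enrichment

Element sequences are concatenated per gene with `NNNNNN` separators so no
k-mer window spans two elements; counting is single-strand over overlapping
windows (motifs are oriented), skipping windows with N. The enrichment score
is a binomial z:

    z = (obs − p̂·W_t) / sqrt(p̂·W_t·(1 − p̂)),   p̂ = count_ref / W_ref

with W the valid window counts. A motif passes when its scores against both
the genomic background and the comparison collection reach the threshold
(default 3.5); results sort by the smaller of the two scores. A pseudocount
(default 1 in the pipeline, 0 in the raw function) regularises
zero-frequency reference k-mers, which otherwise yield a flagged infinite
score.

**Null behaviour of the score.** The z-score treats the reference frequency
as known and the target counts as Gaussian. Neither holds exactly: the
reference estimate carries sampling noise (inflating the variance by
1 + W_t/W_ref), Poisson counts are right-skewed at the expected counts a
6-mer attains on realistic collection sizes, and the two scores share the
same target counts and are therefore strongly correlated. The measured
consequence (computed in the acceptance suite) is that on structureless data
a handful of the 4096 k-mers — a per-k-mer rate of order 5·10⁻⁴, not the
Gaussian 2.3·10⁻⁴ squared — pass both thresholds at scores barely above 3.5,
while a genuinely planted motif scores far higher and ranks first. Absolute
scores are therefore not comparable across corpora or to other published
enrichment scores; only ranking and threshold behaviour within a run are
meaningful.

## Synthetic genomes

The generator emulates the data a genome-browser-based study of this kind
consumes. Its defaults are the study conditions: for each group contrast the
pipeline is meant to detect, the default plants it at the magnitude typical
of real imprinted-vs-autosomal comparisons; remaining values are chosen once
as field-realistic.

* Sequence: i.i.d. bases at G+C 0.42 with region-specific dinucleotide
  adjustments, not a full Markov chain — sufficient for every statistic the
  pipeline computes and much easier to reason about.
* Genes: ~6 exons (2 + Poisson(4)), exon length lognormal (median 140 bp),
  intron length lognormal (median 700 bp), 6% intronless; CDS trims 25% of
  the terminal exons as UTR. Each gene contributes one lognormal "half" to
  the gap on each flank (median 1500 bp), multiplied per group — maternal
  ×1.9, paternal ×2.1 (the planted long-intergenic contrast), autosomal ×1.
* CpG islands: length 400–1000 bp, G+C 0.65, planted CpG density 0.08;
  intronic-island probability 0.30 for labelled groups vs 0.085 autosomal,
  promoter islands 0.4 everywhere.
* Deamination: per gene territory (span + assigned intergenic), d = 0.45
  maternal / 0.40 paternal / 0.60 autosomal outside islands; islands are
  deaminated at their own low rates (0.12 labelled / 0.10 autosomal),
  emulating germline island hypermethylation against hypomethylated
  surroundings.
* Conserved elements: per-class densities per 10 kb reflecting the
  group-specific rates such comparisons report (intronic 1.35/2.04/1.06 for
  maternal/paternal/autosomal, intergenic 1.41/1.29/2.17), coding 20,
  island-hosted 8; lengths lognormal (median 40 bp); one third of raw
  elements are generated below 20 bp so the length filter removes them;
  intronic placement decays exponentially from exon boundaries (scale
  500 bp); scores are per-class gamma draws (shape 6) with class medians
  ~320–500 — the absolute scale is arbitrary, only within-run comparisons
  matter. Elements are placed without mutual overlap: real most-conserved
  tracks are disjoint, and overlapping placements would double-count
  sequence in concatenated motif targets.
* Repeats cover ~8% of noncoding DNA with field-typical family names; the
  L1 density is ×1.3 in labelled territories and the L1M (ancient) fraction
  is 0.81 labelled vs 0.76 autosomal. TF-site probabilities per gene and
  region mirror the association percentages reported for CTCF and YY1 in
  imprinted versus autosomal regions.
* The planted motif (default `GTCGCG`, fold 5) is injected by overwriting
  k-mer copies at random positions inside the target groups' intronic
  elements after deamination, at (fold − 1)·windows/4096 copies.

Everything is deterministic under the config seed; generated bundles are
byte-identical across reruns, as are pipeline reports on identical inputs.

`study_shaped_fixture()` is the end-to-end regression fixture: 58 labelled
genes (28 maternal + 30 paternal) against 1000 autosomal genes on four 3 Mb
chromosomes — the labelled-set size real studies of imprinting use, at a
desk-scale genome.

**What the generator does not emulate.** Real genomes have isochore G+C
structure, nested and overlapping genes, alternative promoters,
lineage-specific repeat landscapes and conservation scores estimated from
actual alignments. Passing tests therefore demonstrate that the machinery
recovers planted effects of the configured magnitudes under clean
conditions; they do not certify power or calibration on real genome-browser
tracks.

## Problem sizes and study designs

The validation studies use these sizes, chosen as the package's own
trade-off between statistical resolution and a desk-scale runtime:

* Oracle equivalence: 200 random genomes ≤ 10 kb / ≤ 10 genes, checked
  per base (zero mismatches required).
* Type-I error: 10⁴ null replicates, n = 50 per group (rank-sum) and
  n = 500 per group at p = 0.3 (proportions) — sizes at which the asymptotic
  tests are the selected branch and their approximations are accurate.
* Random-set calibration: pools of 800 genes, 100 resamples of 58.
* Planted-contrast power: 100 genomes of 200 genes (29+29 labelled) with
  ~12 kb of intron per gene; the intronic-density contrast is planted at
  ×3 for the paternal group — a magnitude chosen so the design's power
  target (≥95% at the highest tier) is attainable with a 29-gene group,
  while the intergenic (×2) and deamination (0.4 vs 0.6) contrasts use the
  default planted magnitudes.
* Motif recovery: 50 genomes with ~60 kb of target element sequence,
  fold-5 plant; null rate measured on 500 kb/2 Mb i.i.d. collections.

## Known limitations

* The enrichment z-score's null tail is heavier than Gaussian (see above);
  threshold 3.5 is a ranking device, not a calibrated significance level.
* UTR classification is merged-exon minus coding cover, not per-isoform UTR
  annotation; genes without CDS annotations have no coding class.
* The generator packs genes without nesting or overlap; overlapping-gene
  handling in the annotator (larger-overlap assignment, empty gaps) is
  therefore exercised only by hand-built unit fixtures.
* χ²/Fisher switching at expected cell < 5 makes borderline tables follow
  Fisher's conservative behaviour; at the study sizes used here the χ²
  branch dominates.
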
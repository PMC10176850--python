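# Methods

## The measurement model

Bisulfite conversion of RNA deaminates unmethylated cytosines to uracil;
after reverse transcription and sequencing they read as T, while
5-methylcytosine (m⁵C) resists conversion and reads as C. At a reference
cytosine with true methylation stoichiometry `m`, a read shows C with
probability

```
P(C) = m · (1 − overconversion_rate) + (1 − m) · (1 − e)
```

where `e` is the conversion efficiency for unmethylated cytosines and the
overconversion rate is the probability that a methylated cytosine
deaminates anyway. The empirical estimate is the non-conversion level
`m̂ = c / (c + t)` over reads showing C or T at the site. Reads showing
any other base are excluded from `m̂` (they carry no conversion
information — they are sequencing noise) but are counted in coverage, so
the 80CT filter acts as a sequencing-noise guard.

The simulator implements exactly this forward model per read molecule,
plus a uniform per-base substitution error applied after conversion.
Spike-in transcripts carry no methylation by construction; their pooled
`Σt / (Σc + Σt)` recovers `e` and is the per-replicate conversion QC.

## Simulation parameters

| parameter | default | meaning |
|---|---|---|
| `conversion_efficiency` | 0.995 | P(unmethylated C → T); a successful conversion with a 0.5 % residual floor |
| `overconversion_rate` | 0 | P(methylated C → T) |
| `seq_error_rate` | 0.001 | per-base uniform substitution after conversion |
| `read_length` | 100 bp | single-end read length |
| `mean_depth` | 60× | fold coverage; read count per transcript is `round(depth·L/read_length)` with uniform starts (a Poisson option exists; the fixed default gives low-variance tests) |
| `n_replicates` | 2 | biological replicates per condition |

The demo transcriptome is 6 transcripts of 1 kb at 50 % GC plus 2
spike-ins, with a planted cluster of three consecutive cytosines at
m = 0 (EV) vs m = 0.8 (restored) — the adjacent-site signature of a
sequence-local methyltransferase target. Reads are simulated from the
sense strand only: RNA bisulfite chemistry acts on a single-stranded
molecule, so no reverse-complement conversion strands exist. Quality
strings are constant (`I`) and never used. Randomness is a pure function
of (arguments, seed); per-(condition, replicate) sub-streams are derived
from the master seed by CRC32-keyed `SeedSequence` spawn keys so
replicates are independent but reproducible, and identical seeds give
byte-identical outputs.

What the generator does **not** emulate: indels, splicing, adapters,
quality decay, rRNA contamination, coverage biases (M-bias, GC bias),
PCR duplicates. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
artifact of real libraries.

## Three-letter mapping

Reads and reference are collapsed C→T so that conversion status cannot
penalize alignment; original read bases are kept for quantification.
Candidate loci come from exact collapsed k-mer seeds (first and mid-read
k-mers, k = 20); each candidate is scored by full-length ungapped
Hamming comparison in collapsed space with a mismatch budget of
`floor(0.05 · read length)`. A read is `unique` iff exactly one locus
attains the minimal mismatch count within budget; ties are `ambiguous`
and only unique alignments enter pileups, mirroring standard bisulfite
practice. Mapping is transcript-space: at desk scale the reference is the
transcript set itself, so splicing and gapped alignment never arise.
Parity with genome-scale bisulfite aligners is not claimed.

## Site calling

Filters, with their field names: coverage ≥ 30 reads (30RC); ≥ 5 reads
showing C (5C); ≥ 80 % of bases C or T (80CT); average non-conversion
level across replicates ≥ 10 % (10MM). A candidate site either passes
30RC/5C/80CT in **both** replicates with the cross-replicate average m
≥ 10 %, or passes in exactly one replicate and is rescued only if that
replicate also clears the stricter 7-C depth (7C) and its own m ≥ 10 % —
in the single-replicate branch no cross-replicate average exists, so the
10MM criterion applies to the passing replicate alone (the only
self-consistent reading). The average m is the unweighted mean of
per-replicate levels; "depth of cytosines" is interpreted as the count
of reads showing C at the site, the only reading under which it is a
per-site quantity. A replicate entirely absent from the pileup counts as
failing, which routes the site into the fallback branch. Rejection
tallies attribute each non-candidate to its first failing filter in the
fixed order 30RC → 80CT → C-depth → 10MM (a reporting convention only).

## Differential methylation

Replicate counts are pooled within condition (a 2×2 C/T-by-condition
table forces pooling with two replicates per arm) and tested with
Fisher's exact test, two-sided by the point-probability convention: the
p-value sums hypergeometric probabilities, at fixed margins, of all
tables no more likely than the observed one. Two-sided conventions
differ between implementations, so this one is pinned by an exhaustive
enumeration oracle in the tests. Correction is Benjamini–Hochberg —
the field default where only "multiple correction" is specified —
with Bonferroni behind a flag, and the method is recorded in output
metadata. A site is differentially methylated when adjusted p < 0.01
and |Δm| > 0.1; the Δ rule is applied two-sided, with a `gain_only`
flag for restoration-style designs where only methylation gain is
expected. The tested set is the union of candidate sites across
conditions that retain pooled C+T evidence in both conditions. Ranking
is by adjusted p, then |Δ| descending, then site key, so full ties are
deterministic.

## Clone analysis

Clones are globally aligned to the unconverted amplicon with
bisulfite-aware scoring: at a reference C, both C and T in the clone
score as matches. The alignment uses an asymmetric substitution matrix
under a standard global aligner with linear gap penalty (−2) and
match/mismatch (+1/−1); the aligner's first optimal traceback is
deterministic. Clones off by more than 20 % in length or below 70 %
bisulfite-aware identity are discarded as unalignable.

Scored positions are CpG-context cytosines in DNA mode (top-strand BSP
convention; reverse-strand amplicons must be reverse-complemented by the
caller) and every cytosine in RNA mode. Incomplete conversion — bisulfite
failing on structured, double-stranded stretches — produces false
methylation calls; the defense is recurrence: a methylated call is
flagged unconverted (X) when the methylated state appears in fewer than
`max(2, 20 % of clones)` clones, i.e. when its placement is not
consistent across clones. A clone is discarded as incomplete-conversion
when more than half of its cytosine calls (C-reads) are flagged **and**
at least 3 calls are flagged. The count floor is this package's own
refinement: without it, on a sparsely methylated amplicon a clone with a
single stray unconverted cytosine would have 100 % of its C-calls
flagged and be discarded, which at e = 0.99 and ~30 cytosines would
wrongly discard roughly a quarter of perfectly good clones, while
genuinely degraded clones (e ≈ 0.7) carry ~9 flagged calls and sail past
the floor. In DNA mode, non-CpG cytosines additionally provide a direct
per-clone conversion rate `t/(c+t)`; clones below 0.95 are discarded.
Defaults expect ≥ 8 clones (DNA) or > 10 (RNA); fewer only downgrades
results to low-confidence. Per-position percents are computed over kept
clones excluding X and missing calls; flagging is a single pass (not
recomputed after discards). Coordinates are 0-based internally with
1-based labels in rendered output, matching transcript-position
nomenclature like "C1324".

## Association layer

Promoter methylation is the unweighted mean β over the promoter's CpGs,
dichotomized at β ≥ 0.30 (boundary inclusive). The 0.30 default is this
package's choice — array β-values below ~0.2 are conventionally
unmethylated and above ~0.3 methylated — and is exposed as a parameter.
Contingency tests are Fisher's exact (2×2, shared implementation with
the differential test) and Pearson's χ² without continuity correction
for r×c tables; the built-in liver-cancer cohort table reproduces four
of its six published p-values to printed precision under these
conventions, and the remaining two (ISHAK, TNM) disagree in the second
decimal under every standard χ² variant, indicating the originals were
computed from slightly different available-case counts than the printed
table. Spearman correlation uses average ranks and the t-approximation;
group comparisons use Student's t with pooled variance (Welch by flag),
with the zero-variance/equal-means degenerate case reported as p = 1.
mRNA half-life after transcriptional arrest is estimated by least
squares on ln(abundance) vs time, `t½ = ln 2 / (−slope)`; non-decaying
series report an infinite half-life with a flag rather than an error.

## Problem sizes and numerical choices

The test suite and acceptance script run everything at desk scale as the
package's own study design: 6×1 kb transcriptomes at 60× for end-to-end
runs (10 seeds), ~500 equally-methylated sites across 5×1 kb transcripts
for null calibration (20 seeds), exhaustive Fisher enumeration over all
2×2 tables with total ≤ 40, 12-clone sets over ~100 bp amplicons for the
clone filter (50 seeds per rate). Monte-Carlo acceptance bands follow
binomial 4σ or exact-interval logic, with single-draw interval checks
pooled across 5 seeds because each carries a nominal 0.1 % miss rate by
construction. Degenerate inputs (no C/T evidence, zero margins, constant
vectors, empty clone sets) return explicit missing/unavailable states
rather than raising, except where the input violates a precondition
(negative counts, non-C planting positions, non-positive abundances).

## Known limitations

Transcript-space ungapped mapping cannot place reads across indels or
splice junctions; the simulator does not generate them. The clone
consistency filter is a recurrence heuristic — a site genuinely
methylated in a single molecule is indistinguishable from a conversion
failure. Survival modeling and genome-scale references are out of scope.
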
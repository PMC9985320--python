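# Methods

This note documents the models, conventions, and numerical choices behind
`tbamkit`, and what the simulator-based tests do and do not establish.

## Coordinates and the 5′ position adjustment

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) and
SAM (1-based POS) are converted at the file boundary. Single-end reads from
this protocol carry the biological 5′ end of the cDNA insert at their start,
so quantification keys on one number per read: for a forward-strand
alignment the mapped position itself, for a reverse-strand alignment the
mapped position **plus the read length**. The adjusted value for a − read is
therefore one past the 5′-terminal base; where a base index is needed (gene
counting), `adj_pos − 1` is used for − reads. SAM input is converted to
0-based first and adjusted second.

Priming locations are defined the same way: each primer, treated as a read,
has adjusted position `anneal_start` (+ targets) or `anneal_end`
(− targets), so a correctly primed read matches its primer's coordinate
exactly and the default assignment tolerance is 0 nt (configurable).

## Primer design

Candidates are every window of length 18–22 nt on the coding strand of a
target whose nearest-neighbor Tm lies in [53, 56] °C, scored by
`|Tm − 55| + 0.5·|len − 20|`. Tm uses the unified nearest-neighbor
thermodynamic parameter set (duplex initiation + stacking ΔH/ΔS, terminal
A·T/G·C penalties) with the SantaLucia entropic salt correction at 50 mM
monovalent cation and 250 nM oligo, as implemented by Biopython's
`Tm_NN(nn_table=DNA_NN3, saltcorr=5)`; the parameter set is frozen, and the
test suite carries an independent hand-written summation oracle that agrees
to < 1 µ°C. The minimum length of 18 nt is the conventional default of
general-purpose primer-design software; the remaining constraints are the
protocol's.

rRNA exclusion removes a candidate iff any of its 8-mers occurs exactly
(0 mismatches) in an rRNA region **or its reverse complement** — read
aligners search both strands by default, and rRNA-homologous primers
dominate libraries made from total RNA regardless of where the homology
sits in the primer. Matching is exact; N never matches anything, including
N (conservative and deterministic).

Spacing selection is a greedy 5′→3′ scan per gene: a position is admissible
when the candidate's 5′ end lies ≥ 20 nt downstream of the 3′-terminal base
of the last admitted primer, and the lowest-penalty candidate at each
admissible position wins (ties: most-upstream coordinate, then smallest
sequence lexicographically). The protocol states the spacing constraint but
not a search procedure; greedy scanning is deterministic and provably
maximal under the pairwise rule — no rejected candidate can be inserted
without a violation — which the suite checks by enumeration. Identical
inputs produce byte-identical manifests.

## Trimming and mapping

Poly(A) trimming reimplements 3′-adapter semantics against an A₂₀ adapter:
every placement is scored, a placement qualifies when its matched length is
≥ 10 and its mismatches are ≤ ⌊0.1 × matched length⌋, and the winner has
minimal errors, then the longest match, then the leftmost start; the read
is cut from the match start. This is deterministic, needs no subprocess,
and is proven equivalent to an exhaustive placement oracle.

The internal mapper reproduces best-stratum, single-report, quality-blind
end-to-end alignment with ≤ 2 mismatches (the `-v 2 -k 1 --best` behavior).
Because an aligner's internal tie order is unspecified, ours is fixed and
documented: lowest mismatch count, then contig id, then coordinate, then
forward before reverse. Candidates are found by pigeonhole seeding (split
the read into `max_mismatches + 1` chunks; any admissible placement
contains one chunk exactly) and verified by full mismatch counting, which
makes the mapper exact, as the naive sliding-window oracle confirms. It is
intended for fixture- and simulator-scale genomes (≲ a few hundred kb);
externally produced SAM/bowtie-legacy alignments are the supported route
for full bacterial genomes.

## Quantification conventions

- Gene counting: a read counts for a gene iff its 5′ base lies at
  transcript offset ∈ [30, L − 30) and strands agree; reads falling in two
  genes' countable windows are dropped and logged (deterministic,
  conservative). A CDS shorter than 60 nt has an empty countable window
  (warning, not error).
- rpm: counts divided by the per-sample total of feature counts, × 10⁶, so
  reported rpm sums to ≤ 10⁶. The reporting threshold is **strictly** more
  than 100 reads (gene mode); primer mode reports all primers, normalized
  per million primer-mapped reads. A zero denominator flags the sample and
  yields NaN, never a silent zero.
- Gene expression from a multi-primer panel is the median of the gene's
  primer rpms (mean of the middle two when even), robust to single primers
  with atypical efficiency.
- Mispriming: unmapped reads are split at 20 nt; a head mapping to a
  priming location defines an event, and the tail locates the off-target
  template when it is ≥ 15 nt (shorter tails are too unspecific to place
  and are reported UNRESOLVED).
- Replicate agreement: Pearson r of log₁₀ rpm per sample pair, and the
  median across features of the SD (ddof = 1) of log₂ rpm across samples.
  The feature mask requires > 100 reads in **every** compared sample; the
  joint mask is the default for pairwise statistics.

## Switching estimators and depth planning

The knockout estimator measures the **per-sample-pair** switching rate:
reads of a deleted feature under the knockout barcode can only have
switched in, from any of the `n` target-containing samples, so
`rate = (ko/wt)/n`. The mixed-species estimator measures the overall
fraction of misassigned molecules (`foreign/total`); the two are related by
a factor of (pool size − 1) under uniform switching.

Single-pool depth: reaching ≥ `min_reads` on the least-abundant of a set of
genes requires scaling the observed profile by `min_reads / c_min`, i.e.
`ceil(min_reads / c_min · Σc)` reads. A redistribution plan splits the
descending-sorted genes into consecutive near-equal groups (⌈n/k⌉ then
⌊n/k⌋, larger groups first) and sums the per-group requirements; the fold
reduction is the single-pool requirement over that sum. In exact arithmetic
the fold reduction is ≥ 1 for any descending grouping, with equality iff
within-group skew everywhere equals the whole-set skew; integer round-up
(reads are discrete) can perturb the ratio by at most one read per group.

## Simulator

The generator emulates: a random genome with non-overlapping genes on both
strands plus designated rRNA regions; log-normal relative abundances;
uniform fragmentation within genes; pure-A poly(A) tails; per-sample
barcoding; uniform-destination barcode switching; and, in targeted mode,
primer choice ∝ target abundance × per-primer efficiency (equal by
default) with chimeric misprimes (primer head + uniformly drawn off-target
body). One integer seed drives per-stage substreams
(`SeedSequence(seed, spawn_key=(stage,))`), so outputs are byte-identical
per seed and adding stages never perturbs earlier draws.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `abundance_sigma` | 1.8 | Φ(1.8 − z₀.₀₁) ≈ 0.30: the top 1% of genes carry ≈ 30% of mRNA reads, the skew typical of bacterial transcriptomes |
| `fragment_length_range` | 28–40 nt | short size-selected fragments; with `read_length` 50 every read shows either its whole insert plus ≥ 10 tail bases or pure insert, so trimming is always decisive |
| `polya_tail_range` | 12–25 nt | in-vitro tailing lengths; ≥ min overlap of the trimmer |
| `read_length` | 50 nt | a typical short-read single-end configuration |
| `rrna_fraction` | 0 | rRNA-depleted input; total-RNA input corresponds to ≈ 0.9 |
| `misprime_rate` | 0 (0.1 in recovery tests) | matches the ≈ 90% specific-priming level observed for rRNA-filtered panels; a simulator setting, not a measured constant |
| `switch_rate` | 0 | per-sample-pair misassignment probability; total misassignment is `switch_rate × (n_samples − 1)` |

`switch_rate` is deliberately defined per pair, not in total, because the
per-pair rate is what the knockout estimator measures; defining it any
other way would make "inject r, recover r" hold only up to a pool-size
factor.

What the simulator does **not** model: sequencing errors and quality
scores, positional fragmentation bias, rRNA-depletion chemistry beyond the
`rrna_fraction` knob, template-switching artifacts, primer-efficiency
variation (available as a knob but flat by default), and operon structure.
Passing recovery tests therefore demonstrates the correctness of the
computational pipeline under the stated generative model, not the
biochemical performance of any protocol on real libraries.

## Problem sizes in the test suite

Recovery tests run at the scale where their statistical claims are sharp
but the suite stays fast: the knockout-recovery experiment uses 6 samples
(5 WT + 1 knockout) × 10⁵ reads on a 20-gene reference, giving a standard
error ≈ 6% of the injected rate; misprime and abundance recovery use one
10⁵-read sample; oracle-equivalence checks use 1000 random reads against a
50 kb genome. The depth-planning demonstration with real expression
profiles requires an external high-depth dataset and is instead exercised
through its exact arithmetic laws (degeneracy, uniform, geometric
brute-force cases) on synthetic profiles.

## Known limitations

- The internal mapper is exact but quadratic in the worst case; it is not a
  replacement for an FM-index aligner on full genomes.
- Gapped/spliced alignment, paired-end reads, and BAM/CRAM are out of
  scope (the protocol is single-end and text formats suffice at this
  scale).
- The equidistant-tie rule in primer assignment (UNASSIGNED with a flag)
  only matters for tolerances > 0; at the default exact-match tolerance
  ties cannot arise for pools satisfying the 20-nt spacing invariant.
- `required_reads_single_pool` treats the observed profile as exact;
  sampling noise in the input counts propagates directly into the plan.
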
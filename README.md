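# tbamkit

A toolkit for the computational side of multiplexed and targeted bacterial
RNA-seq. Bacterial mRNAs lack poly(A) tails, so multiplexed library
protocols add them in vitro, barcode each sample with oligo(dT) primers
during reverse transcription, and pool early; a targeted variant then
enriches the pooled cDNA for chosen transcripts in a single second-strand
synthesis cycle primed by gene-specific oligos carrying a common adapter.
`tbamkit` implements everything such an experiment needs after (and before)
the sequencer:

- **Primer panel design** — exhaustive candidate enumeration under length
  (18–22 nt, optimum 20) and nearest-neighbor melting-temperature
  constraints (53–56 °C, optimum 55 °C), removal of any primer sharing an
  exact 8-mer with an rRNA region on either strand, greedy selection with a
  ≥ 20 nt inter-primer spacing along each transcript, and the common
  adapter `CTTTCCCTACACGACGCTCTTCCGATCT` prepended to every oligo.
- **Read processing** — cutadapt-semantics poly(A) trimming
  (`-a A{20}`, min overlap 10, error rate 0.1), a best-stratum end-to-end
  mapper for fixture-scale genomes (external SAM / bowtie output is the
  path for full-size data), and the reverse-strand 5′ position adjustment
  (`adj_pos = pos + read_length` for − reads) that puts every read's 5′ end
  on a single coordinate.
- **Quantification** — gene counts from adjusted 5′ positions excluding the
  first and last 30 nt of each CDS; reads-per-million with a strict
  \>100-read reporting threshold; read-to-primer assignment by priming
  location; per-primer rpm and median-primer gene expression; split-read
  classification of chimeric nonspecific priming events; pairwise replicate
  correlation on log₁₀ rpm and the median SD of log₂ expression.
- **Crosstalk estimation and depth planning** — the knockout
  (`rate = (ko/wt)/n_samples`) and mixed-species (`rate = foreign/total`)
  barcode-switching estimators, the single-pool depth requirement
  `ceil(min_reads / c_min · Σc)`, and grouped redistribution plans with
  their fold reduction in required reads.
- **A truth-tracked simulator** — skewed (log-normal) abundances, poly(A)
  tailed fragments, per-sample barcodes, switching and mispriming injection,
  with a per-read truth table so every stage above is tested by parameter
  recovery.

## Worked example

```python
import collections, numpy as np
from tbamkit import *

cfg = SimConfig(seed=3, n_genes=20, n_samples=2, reads_per_sample=3000,
                misprime_rate=0.1)
genome, genes = make_reference(cfg)
abundances = sample_abundances(cfg)
cds  = [g for g in genes if g.feature_class == "CDS"]
rrna = [g for g in genes if g.feature_class == "rRNA"]

pool = design_pool(genome, cds, rrna)
print(len(pool.primers), "primers")                 # 133 primers

per_sample, truth = simulate_tbam_reads(genome, genes, abundances, pool, cfg)
reads   = [r for s in sorted(per_sample) for r in per_sample[s]]
trimmed = [r for r in trim_polya_many(reads) if r.sequence]
mapped, unmapped = map_reads(trimmed, genome)
print(len(mapped), "mapped,", len(unmapped), "unmapped")  # 5348 mapped, 652 unmapped

assignments = assign_to_primers(adjust_positions(mapped), pool)
events = classify_misprimes(unmapped, genome, pool)
print(f"misprime rate ~ {len(events) / len(reads):.3f}")  # ~ 0.109 (injected 0.1)

expr = gene_expression_from_primers(primer_expression(assignments, pool), pool)
```

All 5348 end-to-end-mappable reads are specific priming products and land
exactly on their primer's annealing coordinate; the 652 unmapped reads are
the injected chimeras, and the split-read classifier recovers essentially
all of them (652 events against 653 injected), giving back the 10%
nonspecific-priming rate. The median-primer expression in `expr` tracks the
true abundance profile with Spearman ρ ≈ 0.995.

The same operations are available from the shell:

```bash
tbamkit design --genome ref.fa --annotations ref.gff3 --out pool
tbamkit trim --fastq S01.fastq --out S01.trimmed.fastq
tbamkit map --fastq S01.trimmed.fastq --genome ref.fa --out S01.aln.tsv
tbamkit switch-rate --method knockout --ko 3 --wt 153 --n-samples 14
tbamkit plan --counts counts.tsv --groups 5 --out plan.tsv
tbamkit simulate --mode tbam --seed 7 --out-dir sim/
```

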
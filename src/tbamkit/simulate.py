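"""Truth-tracked synthetic data generator for the multiplexed/targeted
RNA-seq workflow.

The generator emulates the data-generating process end to end: a random
genome with annotated genes and rRNA regions, a skewed (log-normal)
transcript abundance profile, fragmentation, in-vitro poly(A) tailing,
per-sample barcoding with cross-sample barcode switching, and — in targeted
mode — second-strand priming with an adjustable rate of chimeric nonspecific
priming (primer head followed by an off-target body). Every emitted read has
a truth record, so each pipeline stage can be tested by parameter recovery
rather than against downloaded data.

One integer seed fully determines all output. Each stage draws from its own
deterministic substream, so adding stages never perturbs earlier draws.

``switch_rate`` is the per-sample-pair switching probability: a read from
sample s is emitted under one specific other sample with probability
``switch_rate`` (total misassignment ``switch_rate * (n_samples - 1)``).
This is the quantity the knockout estimator measures.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .primer_design import PrimerPool
from .reference_io import (
    GeneModel,
    ReferenceGenome,
    SampleRead,
    revcomp,
    write_annotations,
    write_fasta,
    write_fastq,
)

_BASES = np.array(list("ACGT"))

# substream ids
_STREAM_REFERENCE = 0
_STREAM_ABUNDANCE = 1
_STREAM_SAMPLE_BASE = 100


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults describe a small but realistic bacterial setting: short
    size-selected fragments (28-40 nt) with 12-25 nt poly(A) tails read out
    at 50 nt, so a read shows either the complete insert plus >= 10 tailed
    bases (fully trimmable at the default minimum overlap) or pure insert.
    ``abundance_sigma = 1.8`` makes the expected top-1% abundance share ~30%,
    the skew typical of bacterial transcriptomes. ``rrna_fraction`` defaults
    to 0 (rRNA-depleted input); total-RNA input corresponds to ~0.9.
    """

    seed: int = 0
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (250, 400)
    abundance_sigma: float = 1.8
    rrna_fraction: float = 0.0
    n_rrna: int = 2
    rrna_length: int = 400
    n_samples: int = 2
    reads_per_sample: int = 10_000
    fragment_length_range: tuple[int, int] = (28, 40)
    polya_tail_range: tuple[int, int] = (12, 25)
    read_length: int = 50
    misprime_rate: float = 0.0
    switch_rate: float = 0.0
    intergenic: int = 60
    contig_name: str = "sim1"
    genome_length: Optional[int] = None

    def __post_init__(self) -> None:
        for frac in (self.rrna_fraction, self.misprime_rate, self.switch_rate):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        for lo, hi in (
            self.gene_length_range,
            self.fragment_length_range,
            self.polya_tail_range,
        ):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be non-empty and positive")
        if self.switch_rate * max(self.n_samples - 1, 0) > 1.0:
            raise ValueError("switch_rate too high for this many samples")

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


TRUTH_COLUMNS = (
    "read_id",
    "true_sample_id",
    "emitted_sample_id",
    "source",
    "contig",
    "strand",
    "frag_start",
    "frag_end",
    "primer_id",
    "is_misprime",
    "mp_contig",
    "mp_strand",
    "mp_pos",
)


def make_reference(config: SimConfig) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Random genome with non-overlapping genes on both strands plus
    designated rRNA regions; deterministic per seed."""
    rng = _rng(config, _STREAM_REFERENCE)
    pieces: list[str] = []
    genes: list[GeneModel] = []
    cursor = 0

    def spacer() -> None:
        nonlocal cursor
        pieces.append("".join(rng.choice(_BASES, size=config.intergenic)))
        cursor += config.intergenic

    spacer()
    lo, hi = config.gene_length_range
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = "".join(rng.choice(_BASES, size=length))
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:04d}",
                contig=config.contig_name,
                strand=strand,
                start=cursor,
                end=cursor + length,
                feature_class="CDS",
            )
        )
        pieces.append(seq)
        cursor += length
        spacer()
    for j in range(config.n_rrna):
        seq = "".join(rng.choice(_BASES, size=config.rrna_length))
        genes.append(
            GeneModel(
                gene_id=f"rrna_{j + 1}",
                contig=config.contig_name,
                strand="+" if rng.random() < 0.5 else "-",
                start=cursor,
                end=cursor + config.rrna_length,
                feature_class="rRNA",
            )
        )
        pieces.append(seq)
        cursor += config.rrna_length
        spacer()
    if config.genome_length is not None:
        if cursor > config.genome_length:
            raise ValueError(
                f"requested genes need {cursor} nt but genome_length is "
                f"{config.genome_length}"
            )
        pad = config.genome_length - cursor
        if pad:
            pieces.append("".join(rng.choice(_BASES, size=pad)))
            cursor += pad
    genome = ReferenceGenome({config.contig_name: "".join(pieces)})
    return genome, genes


def sample_abundances(config: SimConfig) -> np.ndarray:
    """Log-normal relative abundances over the mRNA genes, summing to 1."""
    rng = _rng(config, _STREAM_ABUNDANCE)
    if config.n_genes == 0:
        return np.array([])
    if config.abundance_sigma == 0:
        return np.full(config.n_genes, 1.0 / config.n_genes)
    w = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=config.n_genes)
    return w / w.sum()


def top_share(abundances: np.ndarray, top_fraction: float = 0.01) -> float:
    """Abundance share carried by the top ``top_fraction`` of genes (at least
    one gene)."""
    if len(abundances) == 0:
        return float("nan")
    k = max(1, int(round(top_fraction * len(abundances))))
    srt = np.sort(abundances)[::-1]
    return float(srt[:k].sum() / srt.sum())


def _pick_emitted(
    true_idx: int, u: float, target: int, config: SimConfig
) -> int:
    total = config.switch_rate * (config.n_samples - 1)
    if u >= total or config.n_samples < 2:
        return true_idx
    # target is uniform over the other samples
    return target if target < true_idx else target + 1


def _fragment(
    gene: GeneModel, genome: ReferenceGenome, flen: int, offset_frac: float
) -> tuple[int, int, str]:
    """Uniform fragment of length <= flen inside the gene, in transcript
    orientation. Returns genomic (start, end, sequence_5'->3')."""
    glen = gene.length
    flen = min(flen, glen)
    max_off = glen - flen
    off = int(offset_frac * (max_off + 1))
    off = min(off, max_off)
    if gene.strand == "+":
        start = gene.start + off
        end = start + flen
        seq = genome.fetch(gene.contig, start, end)
    else:
        end = gene.end - off
        start = end - flen
        seq = revcomp(genome.fetch(gene.contig, start, end))
    return start, end, seq


def simulate_bam_reads(
    genome: ReferenceGenome,
    genes: Sequence[GeneModel],
    abundances: np.ndarray,
    config: SimConfig,
) -> tuple[dict[str, list[SampleRead]], pd.DataFrame]:
    """Whole-transcriptome mode: fragment, tail, barcode, switch.

    Per read: a source is drawn (an rRNA region with probability
    ``rrna_fraction``, else a gene proportional to abundance), a fragment is
    placed uniformly within it, a poly(A) tail appended, the result truncated
    to ``read_length``, and the read emitted under its own sample id except
    for switching events. Returns reads grouped by emitted sample plus the
    truth table.
    """
    mrna = [g for g in genes if g.feature_class == "CDS"]
    rrna = [g for g in genes if g.feature_class == "rRNA"]
    if len(mrna) != len(abundances):
        raise ValueError("abundance vector does not match mRNA gene count")
    if config.rrna_fraction > 0 and not rrna:
        raise ValueError("rrna_fraction > 0 but no rRNA regions")
    samples = config.sample_ids()
    per_sample: dict[str, list[SampleRead]] = {s: [] for s in samples}
    rows: list[tuple] = []
    R = config.reads_per_sample
    fmin, fmax = config.fragment_length_range
    tmin, tmax = config.polya_tail_range
    for si, sample in enumerate(samples):
        rng = _rng(config, _STREAM_SAMPLE_BASE + si)
        use_rrna = rng.random(R) < config.rrna_fraction
        gene_idx = (
            rng.choice(len(mrna), size=R, p=abundances)
            if len(mrna)
            else np.zeros(R, dtype=int)
        )
        rrna_idx = rng.integers(0, max(len(rrna), 1), size=R)
        flens = rng.integers(fmin, fmax + 1, size=R)
        offs = rng.random(R)
        tails = rng.integers(tmin, tmax + 1, size=R)
        switch_u = rng.random(R)
        switch_t = rng.integers(0, max(config.n_samples - 1, 1), size=R)
        for k in range(R):
            if use_rrna[k]:
                gene = rrna[int(rrna_idx[k])]
            else:
                if not len(mrna):
                    raise ValueError("no mRNA genes to draw reads from")
                gene = mrna[int(gene_idx[k])]
            start, end, frag = _fragment(gene, genome, int(flens[k]), float(offs[k]))
            seq = (frag + "A" * int(tails[k]))[: config.read_length]
            ei = _pick_emitted(si, float(switch_u[k]), int(switch_t[k]), config)
            emitted = samples[ei]
            read_id = f"{sample}.{k}"
            per_sample[emitted].append(SampleRead(read_id, emitted, seq, None))
            rows.append(
                (
                    read_id, sample, emitted, gene.gene_id, gene.contig,
                    gene.strand, start, end, None, False, None, None, None,
                )
            )
    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return per_sample, truth


def simulate_tbam_reads(
    genome: ReferenceGenome,
    genes: Sequence[GeneModel],
    abundances: np.ndarray,
    pool: PrimerPool,
    config: SimConfig,
    efficiencies: Optional[np.ndarray] = None,
) -> tuple[dict[str, list[SampleRead]], pd.DataFrame]:
    """Targeted mode: second-strand priming from a designed pool.

    Per read a primer is drawn with probability proportional to its target's
    abundance times a per-primer efficiency (equal by default); the read is
    the primer sequence followed by the transcript continuation downstream of
    the annealing site (clipped at the gene 3' end), or — with probability
    ``misprime_rate`` — by a body drawn from a uniformly random off-target
    locus, then poly(A)-tailed and truncated. ``abundances`` may be a single
    vector or an (n_samples, n_genes) matrix for per-sample profiles
    (e.g. a knockout design).
    """
    if not pool.primers:
        raise ValueError("primer pool is empty")
    mrna = [g for g in genes if g.feature_class == "CDS"]
    gene_by_id = {g.gene_id: g for g in mrna}
    gene_pos = {g.gene_id: i for i, g in enumerate(mrna)}
    for p in pool.primers:
        if p.gene_id not in gene_by_id:
            raise ValueError(f"pool primer targets unknown gene {p.gene_id!r}")
    ab = np.asarray(abundances, dtype=float)
    if ab.ndim == 1:
        ab = np.tile(ab, (config.n_samples, 1))
    if ab.shape != (config.n_samples, len(mrna)):
        raise ValueError("abundances must be (n_genes,) or (n_samples, n_genes)")
    eff = (
        np.ones(len(pool.primers))
        if efficiencies is None
        else np.asarray(efficiencies, dtype=float)
    )
    if len(eff) != len(pool.primers):
        raise ValueError("efficiencies must match pool size")
    samples = config.sample_ids()
    per_sample: dict[str, list[SampleRead]] = {s: [] for s in samples}
    rows: list[tuple] = []
    R = config.reads_per_sample
    fmin, fmax = config.fragment_length_range
    tmin, tmax = config.polya_tail_range
    contig_names = sorted(genome.contigs)
    contig_lens = np.array([len(genome.contigs[c]) for c in contig_names])
    for si, sample in enumerate(samples):
        rng = _rng(config, _STREAM_SAMPLE_BASE + si)
        weights = np.array(
            [ab[si, gene_pos[p.gene_id]] for p in pool.primers]
        ) * eff
        total_w = weights.sum()
        if total_w == 0:
            raise ValueError(f"sample {sample}: all primer weights are zero")
        weights = weights / total_w
        primer_idx = rng.choice(len(pool.primers), size=R, p=weights)
        flens = rng.integers(fmin, fmax + 1, size=R)
        tails = rng.integers(tmin, tmax + 1, size=R)
        mis_u = rng.random(R)
        mis_contig = rng.integers(0, len(contig_names), size=R)
        mis_off = rng.random(R)
        mis_strand = rng.random(R)
        switch_u = rng.random(R)
        switch_t = rng.integers(0, max(config.n_samples - 1, 1), size=R)
        for k in range(R):
            p = pool.primers[int(primer_idx[k])]
            gene = gene_by_id[p.gene_id]
            cont = max(int(flens[k]) - len(p.sequence), 0)
            is_mis = bool(mis_u[k] < config.misprime_rate)
            mp_contig = mp_strand = None
            mp_pos = None
            if is_mis:
                ci = int(mis_contig[k])
                cname = contig_names[ci]
                clen = int(contig_lens[ci])
                body_len = min(cont, clen)
                bstart = int(mis_off[k] * (clen - body_len + 1))
                bstart = min(bstart, clen - body_len)
                body_fwd = genome.fetch(cname, bstart, bstart + body_len)
                if mis_strand[k] < 0.5:
                    body, mp_strand, mp_pos = body_fwd, "+", bstart
                else:
                    body, mp_strand, mp_pos = (
                        revcomp(body_fwd), "-", bstart + body_len,
                    )
                mp_contig = cname
                frag_start, frag_end = p.anneal_start, p.anneal_end
            else:
                if p.target_strand == "+":
                    avail = gene.end - p.anneal_end
                    c = min(cont, avail)
                    body = genome.fetch(p.contig, p.anneal_end, p.anneal_end + c)
                    frag_start, frag_end = p.anneal_start, p.anneal_end + c
                else:
                    avail = p.anneal_start - gene.start
                    c = min(cont, avail)
                    body = revcomp(
                        genome.fetch(p.contig, p.anneal_start - c, p.anneal_start)
                    )
                    frag_start, frag_end = p.anneal_start - c, p.anneal_end
            seq = (p.sequence + body + "A" * int(tails[k]))[: config.read_length]
            ei = _pick_emitted(si, float(switch_u[k]), int(switch_t[k]), config)
            emitted = samples[ei]
            read_id = f"{sample}.{k}"
            per_sample[emitted].append(SampleRead(read_id, emitted, seq, None))
            rows.append(
                (
                    read_id, sample, emitted, p.gene_id, p.contig,
                    p.target_strand, frag_start, frag_end, p.primer_id,
                    is_mis, mp_contig, mp_strand, mp_pos,
                )
            )
    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return per_sample, truth


def write_run(
    out_dir: str | Path,
    genome: ReferenceGenome,
    genes: Sequence[GeneModel],
    per_sample: dict[str, list[SampleRead]],
    truth: pd.DataFrame,
    config: SimConfig,
) -> None:
    """Write FASTQ per sample, truth TSV, reference FASTA + GFF3, and a JSON
    echo of the configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(genome, out / "reference.fa")
    write_annotations(genes, out / "reference.gff3", "gff3")
    for sample, reads in per_sample.items():
        write_fastq(reads, out / f"{sample}.fastq")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
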
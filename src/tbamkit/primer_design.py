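"""Second-strand primer pool design for targeted enrichment.

Primers are forward primers taken directly from the coding (sense) strand of
each target: they anneal to the first-strand cDNA and template second-strand
synthesis at a defined transcript coordinate. The pool is built in four
stages, each exposed separately:

1. exhaustive window enumeration under length and melting-temperature
   constraints (``generate_candidates``),
2. removal of any candidate sharing an exact 8-mer (either strand) with an
   rRNA region, since rRNA-homologous primers dominate libraries made from
   total RNA (``filter_rrna_words``),
3. greedy 5'->3' selection enforcing a minimum spacing between consecutive
   primers on the same transcript (``select_spaced``),
4. prepending the common amplification adapter (``append_adapter``).

Melting temperatures use the unified nearest-neighbor thermodynamic model
(Allawi & SantaLucia parameter set) at 50 mM monovalent cation and 250 nM
oligo; the parameter set is fixed, and changing it is an explicit config
choice, never silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .reference_io import GeneModel, ReferenceGenome, revcomp

DEFAULT_ADAPTER = "CTTTCCCTACACGACGCTCTTCCGATCT"


@dataclass
class DesignParams:
    """Constraints for primer candidate generation and selection.

    Defaults follow the targeted-panel design used for bacterial transcripts:
    20-nt optimum (18-22 allowed), Tm window 53-56 degC with a 55 degC
    optimum, 8-nt exact-match rRNA exclusion, and >= 20 nt between the 3' end
    of one primer and the 5' end of the next on the same transcript.
    """

    opt_len: int = 20
    max_len: int = 22
    min_len: int = 18
    tm_min: float = 53.0
    tm_opt: float = 55.0
    tm_max: float = 56.0
    rrna_word: int = 8
    min_spacing: int = 20
    adapter: str = DEFAULT_ADAPTER
    monovalent_mM: float = 50.0
    oligo_nM: float = 250.0

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.opt_len <= self.max_len):
            raise ValueError("need min_len <= opt_len <= max_len")
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ValueError("need tm_min <= tm_opt <= tm_max")
        if self.rrna_word < 1:
            raise ValueError("rrna_word must be >= 1")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")


@dataclass(frozen=True)
class PrimerCandidate:
    gene_id: str
    contig: str
    target_strand: str
    anneal_start: int  # 0-based half-open genomic coordinates
    anneal_end: int
    sequence: str  # coding-strand subsequence, 5'->3' along the transcript
    tm: float
    penalty: float
    transcript_offset: int  # 5' end position along the transcript

    @property
    def primer_id(self) -> str:
        return (
            f"{self.gene_id}:{self.anneal_start}-{self.anneal_end}"
            f"({self.target_strand})"
        )

    @property
    def match_coordinate(self) -> int:
        """Genomic coordinate a correctly-primed read's adjusted 5' position
        lands on: anneal_start for + targets, anneal_end for - targets (the
        reverse-strand position adjustment yields a one-past-the-end value)."""
        return self.anneal_start if self.target_strand == "+" else self.anneal_end


@dataclass
class PrimerPool:
    primers: list[PrimerCandidate]
    oligos: list[str] = field(default_factory=list)
    pool_id: str = "pool"

    def primer_by_id(self, primer_id: str) -> PrimerCandidate:
        for p in self.primers:
            if p.primer_id == primer_id:
                return p
        raise KeyError(primer_id)

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.primers:
            seen.setdefault(p.gene_id, None)
        return list(seen)


def melting_temperature(sequence: str, params: Optional[DesignParams] = None) -> float:
    """Nearest-neighbor duplex Tm (degC) of a DNA oligo.

    Unified NN table (duplex initiation + stacking enthalpies/entropies),
    SantaLucia entropy salt correction at ``monovalent_mM`` and an oligo
    concentration of ``oligo_nM``. Deterministic; N is rejected.
    """
    params = params or DesignParams()
    if len(sequence) < 8:
        raise ValueError("sequence shorter than 8 nt")
    if set(sequence) - set("ACGT"):
        raise ValueError(f"non-ACGT characters in {sequence!r}")
    return float(
        _mt.Tm_NN(
            sequence,
            nn_table=_mt.DNA_NN3,
            Na=params.monovalent_mM,
            dnac1=params.oligo_nM,
            dnac2=0,
            saltcorr=5,
        )
    )


def generate_candidates(
    gene: GeneModel,
    genome: ReferenceGenome,
    params: Optional[DesignParams] = None,
) -> list[PrimerCandidate]:
    """Enumerate every coding-strand window of allowed length whose Tm falls
    inside the window, scored by ``|tm - tm_opt| + 0.5 * |len - opt_len|``.

    Candidates are sorted by transcript coordinate, then penalty. A gene
    shorter than ``min_len`` yields an empty list.
    """
    params = params or DesignParams()
    cds = gene.transcript_seq(genome)
    n = len(cds)
    out: list[PrimerCandidate] = []
    for offset in range(n - params.min_len + 1):
        for length in range(params.min_len, params.max_len + 1):
            if offset + length > n:
                break
            window = cds[offset : offset + length]
            if "N" in window:
                continue
            tm = melting_temperature(window, params)
            if not (params.tm_min <= tm <= params.tm_max):
                continue
            penalty = abs(tm - params.tm_opt) + 0.5 * abs(length - params.opt_len)
            if gene.strand == "+":
                a_start = gene.start + offset
                a_end = a_start + length
            else:
                a_end = gene.end - offset
                a_start = a_end - length
            out.append(
                PrimerCandidate(
                    gene_id=gene.gene_id,
                    contig=gene.contig,
                    target_strand=gene.strand,
                    anneal_start=a_start,
                    anneal_end=a_end,
                    sequence=window,
                    tm=tm,
                    penalty=penalty,
                    transcript_offset=offset,
                )
            )
    out.sort(key=lambda c: (c.transcript_offset, c.penalty, c.sequence))
    return out


def rrna_word_set(
    rrna_regions: Sequence[GeneModel],
    genome: ReferenceGenome,
    word: int,
) -> set[str]:
    """All exact ``word``-mers present in the rRNA regions, both strands.
    Words containing N are excluded (N never matches)."""
    words: set[str] = set()
    for region in rrna_regions:
        seq = genome.fetch(region.contig, region.start, region.end)
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - word + 1):
                w = s[i : i + word]
                if "N" not in w:
                    words.add(w)
    return words


def filter_rrna_words(
    candidates: Sequence[PrimerCandidate],
    rrna_regions: Sequence[GeneModel],
    genome: ReferenceGenome,
    params: Optional[DesignParams] = None,
) -> list[PrimerCandidate]:
    """Drop any candidate containing an exact ``rrna_word``-mer that occurs in
    an rRNA region on either strand; everything else passes unchanged."""
    params = params or DesignParams()
    if not rrna_regions:
        return list(candidates)
    words = rrna_word_set(rrna_regions, genome, params.rrna_word)
    kept = []
    for cand in candidates:
        seq = cand.sequence
        k = params.rrna_word
        if any(seq[i : i + k] in words for i in range(len(seq) - k + 1)):
            continue
        kept.append(cand)
    return kept


def select_spaced(
    candidates: Sequence[PrimerCandidate],
    params: Optional[DesignParams] = None,
    pool_id: str = "pool",
) -> PrimerPool:
    """Greedy 5'->3' per-gene selection under the spacing rule.

    Scanning transcript coordinates in order, a position is admissible when
    the candidate's 5' end lies at least ``min_spacing`` nt downstream of the
    3'-terminal base of the last admitted primer; at each admissible position
    the lowest-penalty candidate wins (ties: lexicographically smallest
    sequence). The result is maximal: no rejected candidate can be added
    without violating spacing against its closest upstream selected primer.
    """
    params = params or DesignParams()
    by_gene: dict[str, list[PrimerCandidate]] = {}
    for c in candidates:
        by_gene.setdefault(c.gene_id, []).append(c)
    selected: list[PrimerCandidate] = []
    for gene_id in by_gene:
        cands = sorted(
            by_gene[gene_id],
            key=lambda c: (c.transcript_offset, c.penalty, c.sequence),
        )
        last_3p: Optional[int] = None  # transcript offset of 3'-terminal base
        i = 0
        while i < len(cands):
            offset = cands[i].transcript_offset
            group = [c for c in cands if c.transcript_offset == offset]
            i += len(group)
            if last_3p is not None and offset - last_3p < params.min_spacing:
                continue
            best = min(group, key=lambda c: (c.penalty, c.sequence))
            selected.append(best)
            last_3p = offset + len(best.sequence) - 1
    return PrimerPool(primers=selected, pool_id=pool_id)


def append_adapter(
    pool: PrimerPool, params: Optional[DesignParams] = None
) -> PrimerPool:
    """Prepend the common adapter to every primer to form synthesis oligos."""
    params = params or DesignParams()
    oligos = [params.adapter + p.sequence for p in pool.primers]
    return PrimerPool(primers=list(pool.primers), oligos=oligos, pool_id=pool.pool_id)


def design_pool(
    genome: ReferenceGenome,
    targets: Sequence[GeneModel],
    rrna_regions: Sequence[GeneModel],
    params: Optional[DesignParams] = None,
    pool_id: str = "pool",
) -> PrimerPool:
    """Full design pipeline: enumerate, rRNA-filter, space, add adapter."""
    params = params or DesignParams()
    candidates: list[PrimerCandidate] = []
    for gene in targets:
        candidates.extend(generate_candidates(gene, genome, params))
    candidates = filter_rrna_words(candidates, rrna_regions, genome, params)
    pool = select_spaced(candidates, params, pool_id=pool_id)
    return append_adapter(pool, params)


def validate_pool(
    pool: PrimerPool,
    genome: ReferenceGenome,
    rrna_regions: Sequence[GeneModel],
    params: Optional[DesignParams] = None,
) -> list[str]:
    """Independent invariant check; returns a list of violation messages.

    Rescans sequences and coordinates from scratch: oligo structure, genome
    identity of each primer, Tm window, rRNA word exclusion via substring
    search over both strands of every rRNA region, and spacing per gene.
    """
    params = params or DesignParams()
    problems: list[str] = []
    if pool.oligos and len(pool.oligos) != len(pool.primers):
        problems.append("oligo count differs from primer count")
    for idx, p in enumerate(pool.primers):
        if not (params.min_len <= len(p.sequence) <= params.max_len):
            problems.append(f"{p.primer_id}: length {len(p.sequence)} out of range")
        genomic = genome.fetch(p.contig, p.anneal_start, p.anneal_end)
        expected = genomic if p.target_strand == "+" else revcomp(genomic)
        if p.sequence != expected:
            problems.append(f"{p.primer_id}: sequence != genome coding strand")
        tm = melting_temperature(p.sequence, params)
        if not (params.tm_min <= tm <= params.tm_max):
            problems.append(f"{p.primer_id}: Tm {tm:.2f} outside window")
        if pool.oligos:
            oligo = pool.oligos[idx]
            if not oligo.startswith(params.adapter):
                problems.append(f"{p.primer_id}: oligo lacks adapter prefix")
            if not oligo.endswith(p.sequence):
                problems.append(f"{p.primer_id}: oligo does not end with primer")
        k = params.rrna_word
        for region in rrna_regions:
            rseq = genome.fetch(region.contig, region.start, region.end)
            both = (rseq, revcomp(rseq))
            for i in range(len(p.sequence) - k + 1):
                w = p.sequence[i : i + k]
                if "N" not in w and any(w in s for s in both):
                    problems.append(
                        f"{p.primer_id}: shares {k}-mer {w} with {region.gene_id}"
                    )
                    break
            else:
                continue
            break
    by_gene: dict[str, list[PrimerCandidate]] = {}
    for p in pool.primers:
        by_gene.setdefault(p.gene_id, []).append(p)
    for gene_id, primers in by_gene.items():
        ordered = sorted(primers, key=lambda p: p.transcript_offset)
        for prev, nxt in zip(ordered, ordered[1:]):
            prev_3p = prev.transcript_offset + len(prev.sequence) - 1
            if nxt.transcript_offset - prev_3p < params.min_spacing:
                problems.append(
                    f"{gene_id}: spacing violation between "
                    f"{prev.primer_id} and {nxt.primer_id}"
                )
    return problems


MANIFEST_COLUMNS = (
    "pool_id",
    "primer_id",
    "gene_id",
    "contig",
    "strand",
    "anneal_start",
    "anneal_end",
    "primer_seq",
    "oligo_seq",
    "tm",
    "penalty",
)


def write_manifest(pool: PrimerPool, path: str | Path) -> None:
    """Primer manifest TSV; byte-identical for identical inputs."""
    with open(path, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for i, p in enumerate(pool.primers):
            oligo = pool.oligos[i] if pool.oligos else ""
            fh.write(
                "\t".join(
                    [
                        pool.pool_id,
                        p.primer_id,
                        p.gene_id,
                        p.contig,
                        p.target_strand,
                        str(p.anneal_start),
                        str(p.anneal_end),
                        p.sequence,
                        oligo,
                        f"{p.tm:.4f}",
                        f"{p.penalty:.4f}",
                    ]
                )
                + "\n"
            )


def read_manifest(path: str | Path) -> PrimerPool:
    primers: list[PrimerCandidate] = []
    oligos: list[str] = []
    pool_id = "pool"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MANIFEST_COLUMNS:
            raise ValueError(f"{path}: unexpected manifest header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            pool_id = f[0]
            start, end = int(f[5]), int(f[6])
            strand = f[4]
            # Transcript offsets are only ever compared within a gene, so a
            # per-gene constant shift is harmless: use the genomic coordinate
            # of the 5' end, negated for - targets to preserve 5'->3' order.
            offset = start if strand == "+" else -end
            primers.append(
                PrimerCandidate(
                    gene_id=f[2],
                    contig=f[3],
                    target_strand=strand,
                    anneal_start=start,
                    anneal_end=end,
                    sequence=f[7],
                    tm=float(f[9]),
                    penalty=float(f[10]),
                    transcript_offset=offset,
                )
            )
            oligos.append(f[8])
    return PrimerPool(primers=primers, oligos=oligos, pool_id=pool_id)


def write_oligos_fasta(pool: PrimerPool, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(pool.primers):
            oligo = pool.oligos[i] if pool.oligos else p.sequence
            fh.write(f">{pool.pool_id}|{p.primer_id}\n{oligo}\n")
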
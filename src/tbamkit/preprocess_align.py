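"""Poly(A) trimming, end-to-end read mapping, and 5' position adjustment.

The trimmer reimplements 3'-adapter semantics (error rate, minimum overlap)
for a poly(A) tail adapter so the behavior is deterministic and testable
without a subprocess. The mapper is an exact best-stratum, single-report
aligner for small reference sequences: every end-to-end placement on both
strands with at most ``max_mismatches`` mismatches is considered, exactly one
alignment from the lowest-mismatch stratum is reported, and ties are broken
by (contig id, coordinate, forward before reverse). It is intended for
fixture- and simulator-scale genomes; externally produced SAM/bowtie files
are the supported path for full-size data and enter through
``reference_io.read_alignments``.

Reverse-strand alignments get their mapped position adjusted by adding the
read length, so the adjusted coordinate always marks the 5' end of the read
in transcript orientation (one-past-the-end for - reads).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .reference_io import RawAlignment, ReferenceGenome, SampleRead, revcomp


@dataclass
class TrimParams:
    """Cutadapt-style 3' adapter trimming parameters for poly(A) tails."""

    tail_adapter: str = "A" * 20
    min_overlap: int = 10
    max_error_rate: float = 0.1

    def __post_init__(self) -> None:
        if not (1 <= self.min_overlap <= len(self.tail_adapter)):
            raise ValueError("need 1 <= min_overlap <= len(tail_adapter)")
        if not (0 <= self.max_error_rate < 0.5):
            raise ValueError("need 0 <= max_error_rate < 0.5")


@dataclass
class AdjustedAlignment(RawAlignment):
    """RawAlignment plus the strand-adjusted 5' coordinate."""

    adj_pos: int = -1

    def __post_init__(self) -> None:
        super().__post_init__()
        expected = self.pos if self.strand == "+" else self.pos + self.read_length
        if self.adj_pos == -1:
            self.adj_pos = expected
        elif self.adj_pos != expected:
            raise ValueError(
                f"read {self.read_id!r}: adj_pos {self.adj_pos} inconsistent "
                f"with strand/pos/read_length"
            )


def trim_polya(read: SampleRead, params: Optional[TrimParams] = None) -> SampleRead:
    """Trim the best-scoring 3' poly(A) adapter occurrence from a read.

    Every placement of the adapter starting at position ``j`` is scored: the
    matched length is the adapter length or the remaining read suffix,
    whichever is shorter; placements shorter than ``min_overlap`` or with
    more than ``floor(max_error_rate * matched_length)`` mismatches are
    discarded. Among qualifying placements the winner has minimal errors,
    then longest match, then leftmost start, and the read is cut from the
    match start to its end (quality trimmed in register). With no qualifying
    placement the read is returned unchanged. N never matches.
    """
    params = params or TrimParams()
    seq = read.sequence
    adapter = params.tail_adapter
    la = len(adapter)
    n = len(seq)
    best: Optional[tuple[int, int, int]] = None  # (errors, -matched, start)
    for j in range(0, n - params.min_overlap + 1):
        m = min(la, n - j)
        allowed = int(params.max_error_rate * m)
        errors = 0
        for i in range(m):
            a, b = seq[j + i], adapter[i]
            if a != b or a == "N":
                errors += 1
                if errors > allowed:
                    break
        else:
            key = (errors, -m, j)
            if best is None or key < best:
                best = key
    if best is None:
        return read
    j = best[2]
    if j == 0:
        return _empty_read(read)
    return SampleRead(
        read.read_id,
        read.sample_id,
        seq[:j],
        read.quality[:j] if read.quality is not None else None,
    )


def _empty_read(read: SampleRead) -> SampleRead:
    """A zero-length insert; bypasses SampleRead's non-empty invariant, which
    applies to sequencer output, not to fully-trimmed inserts."""
    out = object.__new__(SampleRead)
    out.read_id = read.read_id
    out.sample_id = read.sample_id
    out.sequence = ""
    out.quality = "" if read.quality is not None else None
    return out


def trim_polya_many(
    reads: Sequence[SampleRead], params: Optional[TrimParams] = None
) -> list[SampleRead]:
    params = params or TrimParams()
    return [trim_polya(r, params) for r in reads]


class _ContigIndex:
    """Forward sequence plus its reverse complement for strand search."""

    __slots__ = ("name", "fwd", "length")

    def __init__(self, name: str, seq: str):
        self.name = name
        self.fwd = seq
        self.length = len(seq)


def _count_mismatches(a: str, b: str, limit: int) -> int:
    """Mismatches between equal-length strings; N never matches. Aborts early
    once the count exceeds ``limit`` (returns limit + 1)."""
    errors = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            errors += 1
            if errors > limit:
                return errors
    return errors


def _chunk_spans(length: int, parts: int) -> list[tuple[int, int]]:
    """Split [0, length) into ``parts`` near-equal contiguous spans."""
    spans = []
    for k in range(parts):
        lo = k * length // parts
        hi = (k + 1) * length // parts
        if hi > lo:
            spans.append((lo, hi))
    return spans


def map_reads(
    reads: Sequence[SampleRead],
    genome: ReferenceGenome,
    max_mismatches: int = 2,
) -> tuple[list[RawAlignment], list[SampleRead]]:
    """Best-stratum end-to-end mapping of reads against a small genome.

    Candidate placements are found by pigeonhole seeding: a placement with at
    most ``max_mismatches`` mismatches must contain at least one of
    ``max_mismatches + 1`` contiguous read chunks exactly, so exact chunk
    occurrences (string search) enumerate every admissible placement, which
    is then verified by full mismatch counting. Reads with no admissible
    placement are returned unmapped; zero-length reads are unmapped.
    """
    contigs = [_ContigIndex(name, seq) for name, seq in genome.contigs.items()]
    contigs.sort(key=lambda c: c.name)
    mapped: list[RawAlignment] = []
    unmapped: list[SampleRead] = []
    parts = max_mismatches + 1
    for read in reads:
        L = len(read.sequence)
        if L == 0:
            unmapped.append(read)
            continue
        queries = ((read.sequence, "+"), (revcomp(read.sequence), "-"))
        spans = _chunk_spans(L, min(parts, L))
        best: Optional[tuple[int, str, int, int]] = None  # (mm, contig, pos, rev)
        for contig in contigs:
            if L > contig.length:
                continue
            text = contig.fwd
            for query, strand in queries:
                seen: set[int] = set()
                for lo, hi in spans:
                    chunk = query[lo:hi]
                    start = 0
                    while True:
                        hit = text.find(chunk, start)
                        if hit == -1:
                            break
                        start = hit + 1
                        pos = hit - lo
                        if pos < 0 or pos + L > contig.length or pos in seen:
                            continue
                        seen.add(pos)
                        mm = _count_mismatches(
                            query, text[pos : pos + L], max_mismatches
                        )
                        if mm <= max_mismatches:
                            key = (mm, contig.name, pos, 0 if strand == "+" else 1)
                            if best is None or key < best:
                                best = key
        if best is None:
            unmapped.append(read)
        else:
            mm, contig_name, pos, rev = best
            mapped.append(
                RawAlignment(
                    read_id=read.read_id,
                    sample_id=read.sample_id,
                    contig=contig_name,
                    strand="-" if rev else "+",
                    pos=pos,
                    read_length=L,
                    mismatches=mm,
                )
            )
    return mapped, unmapped


def adjust_positions(alignments: Sequence[RawAlignment]) -> list[AdjustedAlignment]:
    """Strand-adjust mapped positions: + reads keep ``pos``; - reads report
    ``pos + read_length``. One output record per input record."""
    out = []
    for a in alignments:
        out.append(
            AdjustedAlignment(
                read_id=a.read_id,
                sample_id=a.sample_id,
                contig=a.contig,
                strand=a.strand,
                pos=a.pos,
                read_length=a.read_length,
                mismatches=a.mismatches,
            )
        )
    return out


def five_prime_index(alignment: AdjustedAlignment) -> int:
    """Genomic index of the read's 5'-terminal base: ``adj_pos`` for + reads,
    ``adj_pos - 1`` for - reads (the adjustment yields one-past-the-end)."""
    return alignment.adj_pos if alignment.strand == "+" else alignment.adj_pos - 1
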
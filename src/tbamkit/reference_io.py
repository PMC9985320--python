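"""Domain types and readers/writers shared by the whole toolkit.

Coordinates are 0-based half-open everywhere inside the package; conversion
to/from 1-based conventions (GFF3, SAM) happens only at file boundaries.
Sample identity travels with each read: either supplied explicitly (one FASTQ
per demultiplexed sample) or embedded in the read id as a ``sample=<id>``
token.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ReferenceGenome:
    """A set of contigs, id -> uppercase A/C/G/T/N sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("reference genome has no contigs")
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("empty contig id")
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"contig {name!r} contains non-DNA characters: {sorted(bad)}"
                )

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs[contig]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


@dataclass(frozen=True)
class GeneModel:
    """An annotated feature: CDS, rRNA region, or other."""

    gene_id: str
    contig: str
    strand: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    feature_class: str = "CDS"  # CDS | rRNA | other

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad coordinates [{self.start}, {self.end}) for {self.gene_id}"
            )
        if self.feature_class not in ("CDS", "rRNA", "other"):
            raise ValueError(f"bad feature_class {self.feature_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def transcript_seq(self, genome: ReferenceGenome) -> str:
        """Feature sequence in transcript (5'->3') orientation."""
        seq = genome.fetch(self.contig, self.start, self.end)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class SampleRead:
    read_id: str
    sample_id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r} has empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length != sequence length"
            )


@dataclass
class RawAlignment:
    read_id: str
    sample_id: str
    contig: str
    strand: str
    pos: int  # 0-based leftmost coordinate on the forward strand
    read_length: int
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.pos < 0 or self.read_length < 1 or self.mismatches < 0:
            raise ValueError(f"bad alignment record for read {self.read_id!r}")


# ---------------------------------------------------------------------------
# Sample-id plumbing
# ---------------------------------------------------------------------------

_SAMPLE_TOKEN = re.compile(r"sample=([^\s;|]+)")


def sample_from_read_id(read_id: str, default: str) -> str:
    """Extract a ``sample=<id>`` token from a read id, else ``default``."""
    m = _SAMPLE_TOKEN.search(read_id)
    return m.group(1) if m else default


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a FASTA file into a ReferenceGenome.

    Sequences are uppercased and U is converted to T. Duplicate or empty
    records raise ParseError.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        if record.id in contigs:
            raise ParseError(f"{path}: duplicate contig id {record.id!r}")
        if not seq:
            raise ParseError(f"{path}: record {record.id!r} has no sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ParseError(
                f"{path}: record {record.id!r} has non-DNA characters {sorted(bad)}"
            )
        contigs[record.id] = seq
    if not contigs:
        raise ParseError(f"{path}: no records")
    return ReferenceGenome(contigs)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotations (GFF3 / BED)
# ---------------------------------------------------------------------------


def _classify_feature(feature_type: str, name: str = "") -> str:
    text = f"{feature_type} {name}".lower()
    if "rrna" in text:
        return "rRNA"
    if feature_type.upper() == "CDS":
        return "CDS"
    return "other"


_GFF_ID = re.compile(r"(?:^|;)\s*(?:ID|gene_id|Name|locus_tag)=([^;]+)")


def read_annotations(
    path: str | Path,
    dialect: str,
    genome: Optional[ReferenceGenome] = None,
) -> list[GeneModel]:
    """Read GFF3 or BED annotations into GeneModel records.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open;
    BED passes through. Records whose interval is empty after conversion are
    rejected with a warning; a contig absent from ``genome`` (when supplied)
    is an error.
    """
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    genes: list[GeneModel] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(fields) < 9:
                        raise ParseError(
                            f"{path}:{lineno}: GFF3 line has {len(fields)} fields"
                        )
                    contig, _source, ftype = fields[0], fields[1], fields[2]
                    start = int(fields[3]) - 1
                    end = int(fields[4])
                    strand = fields[6]
                    attrs = fields[8]
                    m = _GFF_ID.search(attrs)
                    gene_id = m.group(1) if m else f"feature_{lineno}"
                    fclass = _classify_feature(ftype, gene_id)
                else:
                    if len(fields) < 6:
                        raise ParseError(
                            f"{path}:{lineno}: BED line needs >= 6 fields "
                            "(chrom start end name score strand)"
                        )
                    contig = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
                    gene_id = fields[3]
                    strand = fields[5]
                    ftype = fields[6] if len(fields) > 6 else ""
                    fclass = _classify_feature(ftype, gene_id)
            except ParseError:
                raise
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                warnings.warn(
                    f"{path}:{lineno}: empty interval for {gene_id!r}, skipped"
                )
                continue
            if genome is not None:
                if contig not in genome:
                    raise ParseError(
                        f"{path}:{lineno}: unknown contig {contig!r}"
                    )
                if end > len(genome.contigs[contig]):
                    raise ParseError(
                        f"{path}:{lineno}: {gene_id!r} extends past contig end"
                    )
            if gene_id in seen_ids:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen_ids.add(gene_id)
            genes.append(GeneModel(gene_id, contig, strand, start, end, fclass))
    return genes


def write_annotations(
    genes: Iterable[GeneModel], path: str | Path, dialect: str
) -> None:
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for g in genes:
                ftype = {"CDS": "CDS", "rRNA": "rRNA", "other": "region"}[
                    g.feature_class
                ]
                fh.write(
                    f"{g.contig}\ttbamkit\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
        else:
            for g in genes:
                fh.write(
                    f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t"
                    f"{g.strand}\t{g.feature_class}\n"
                )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path, sample_id: Optional[str] = None) -> list[SampleRead]:
    """Read single-end FASTQ. Sample identity comes from ``sample_id`` (or the
    filename stem), overridden per read by a ``sample=<id>`` header token."""
    default = sample_id if sample_id is not None else Path(path).stem
    reads = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            read_id = title.split()[0]
            sample = sample_from_read_id(title, default)
            reads.append(SampleRead(read_id, sample, seq.upper(), qual))
    return reads


def write_fastq(reads: Iterable[SampleRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Alignments (SAM / bowtie legacy / TSV)
# ---------------------------------------------------------------------------


def read_alignments(
    path: str | Path,
    dialect: str,
    genome: Optional[ReferenceGenome] = None,
    sample_id: Optional[str] = None,
) -> list[RawAlignment]:
    """Read SAM or bowtie legacy alignments; unmapped records are skipped.

    Mismatch counts come from the NM tag (SAM) or the mismatch-descriptor
    column (bowtie legacy), defaulting to 0 when absent.
    """
    if dialect not in ("sam", "bowtie_legacy"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    default = sample_id if sample_id is not None else Path(path).stem
    out: list[RawAlignment] = []
    if dialect == "sam":
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped:
                    continue
                length = rec.query_length or rec.infer_query_length() or 0
                if length == 0:
                    continue
                try:
                    nm = int(rec.get_tag("NM"))
                except KeyError:
                    nm = 0
                out.append(
                    RawAlignment(
                        read_id=rec.query_name,
                        sample_id=sample_from_read_id(rec.query_name, default),
                        contig=rec.reference_name,
                        strand="-" if rec.is_reverse else "+",
                        pos=rec.reference_start,
                        read_length=length,
                        mismatches=nm,
                    )
                )
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    raise ParseError(
                        f"{path}:{lineno}: bowtie legacy line has "
                        f"{len(fields)} fields, expected >= 5"
                    )
                name, strand, contig, offset, seq = fields[:5]
                if strand not in ("+", "-"):
                    raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
                mismatches = 0
                if len(fields) >= 8 and fields[7]:
                    mismatches = fields[7].count(":")
                out.append(
                    RawAlignment(
                        read_id=name,
                        sample_id=sample_from_read_id(name, default),
                        contig=contig,
                        strand=strand,
                        pos=int(offset),
                        read_length=len(seq),
                        mismatches=mismatches,
                    )
                )
    if genome is not None:
        for aln in out:
            if aln.contig not in genome:
                raise ParseError(f"alignment on unknown contig {aln.contig!r}")
            if aln.pos + aln.read_length > len(genome.contigs[aln.contig]):
                raise ParseError(
                    f"read {aln.read_id!r} extends past end of contig "
                    f"{aln.contig!r}"
                )
    return out


ALIGNMENT_TSV_COLUMNS = (
    "read_id",
    "sample_id",
    "contig",
    "strand",
    "pos",
    "read_length",
    "mismatches",
)


def write_alignments_tsv(alignments: Iterable[RawAlignment], path: str | Path) -> None:
    from .preprocess_align import AdjustedAlignment  # local import, no cycle at load

    alignments = list(alignments)
    adjusted = bool(alignments) and isinstance(alignments[0], AdjustedAlignment)
    cols = ALIGNMENT_TSV_COLUMNS + (("adj_pos",) if adjusted else ())
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in alignments:
            row = [
                a.read_id,
                a.sample_id,
                a.contig,
                a.strand,
                str(a.pos),
                str(a.read_length),
                str(a.mismatches),
            ]
            if adjusted:
                row.append(str(a.adj_pos))
            fh.write("\t".join(row) + "\n")


def read_alignments_tsv(path: str | Path) -> list[RawAlignment]:
    from .preprocess_align import AdjustedAlignment

    out: list[RawAlignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:7] != list(ALIGNMENT_TSV_COLUMNS):
            raise ParseError(f"{path}: unexpected alignment TSV header")
        adjusted = len(header) > 7 and header[7] == "adj_pos"
        for line in fh:
            f = line.rstrip("\n").split("\t")
            base = dict(
                read_id=f[0],
                sample_id=f[1],
                contig=f[2],
                strand=f[3],
                pos=int(f[4]),
                read_length=int(f[5]),
                mismatches=int(f[6]),
            )
            if adjusted:
                out.append(AdjustedAlignment(adj_pos=int(f[7]), **base))
            else:
                out.append(RawAlignment(**base))
    return out
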
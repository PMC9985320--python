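"""Gene- and primer-level quantification, mispriming, and replicate agreement.

Gene counting uses the adjusted 5' position of each read and excludes the
first and last ``edge_exclusion`` nucleotides of every CDS in transcript
orientation, which avoids edge effects from fragments that straddle gene
boundaries. Targeted (primer-level) expression assigns each read to the
primer whose priming location matches its adjusted 5' position, then
normalizes per million primer-mapped reads; a gene covered by several
primers is summarized by the median primer rpm, which is robust to
individual primers with atypical efficiency.

Nonspecific priming produces chimeric reads (primer head + off-target body)
that fail end-to-end mapping. They are recognized by splitting each unmapped
read: if its first ``head_len`` nucleotides map to a priming location, the
read is a mispriming event and the mapping of the remainder, when long
enough to be specific, locates the off-target template.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .preprocess_align import (
    AdjustedAlignment,
    adjust_positions,
    five_prime_index,
    map_reads,
)
from .primer_design import PrimerPool
from .reference_io import GeneModel, ReferenceGenome, SampleRead

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"


@dataclass
class ExpressionTable:
    """Per-sample, per-feature counts with optional rpm.

    ``counts`` is features x samples (integer). ``rpm`` is populated by
    :func:`compute_rpm`; in gene mode, rpm is reported (non-NaN) only for
    features with strictly more than ``min_reads_report`` reads in that
    sample, while raw counts are always retained.
    """

    counts: pd.DataFrame
    feature_kind: str = "gene"  # gene | primer
    min_reads_report: int = 100
    denominator_policy: str = "all_feature_reads"
    rpm: Optional[pd.DataFrame] = None
    flagged_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gene", "primer"):
            raise ValueError(f"bad feature_kind {self.feature_kind!r}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")


@dataclass(frozen=True)
class PrimerAssignment:
    read_id: str
    sample_id: str
    primer_id: str  # primer id or UNASSIGNED
    match_offset: Optional[int] = None  # signed adj_pos - priming location
    tie: bool = False


@dataclass(frozen=True)
class MisprimeEvent:
    read_id: str
    sample_id: str
    primer_id: str
    resolved: bool
    misprime_contig: Optional[str] = None
    misprime_strand: Optional[str] = None
    misprime_pos: Optional[int] = None  # adjusted 5' coordinate of the body


@dataclass
class AgreementStats:
    """Pairwise replicate agreement on a shared set of reported features."""

    pairwise_r: pd.DataFrame  # samples x samples, Pearson r of log10 rpm
    median_sd_log2fc: float
    n_features: int
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def min_r(self) -> float:
        r = self.pairwise_r.values
        off = r[~np.eye(len(r), dtype=bool)]
        return float(np.nanmin(off)) if off.size else float("nan")


# ---------------------------------------------------------------------------
# Gene-level counting
# ---------------------------------------------------------------------------


def count_gene_reads(
    alignments: Sequence[AdjustedAlignment],
    genes: Sequence[GeneModel],
    edge_exclusion: int = 30,
    sample_ids: Optional[Sequence[str]] = None,
) -> ExpressionTable:
    """Count reads per gene from adjusted 5' positions.

    A read contributes to gene g iff its 5' base falls at a transcript
    offset in ``[edge_exclusion, length - edge_exclusion)`` and the strands
    agree. Reads landing in the countable window of more than one gene are
    dropped and logged. Genes shorter than twice the exclusion get a zero
    countable region (warning).
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        lo = g.start + edge_exclusion
        hi = g.end - edge_exclusion
        if lo >= hi:
            warnings.warn(
                f"gene {g.gene_id}: CDS shorter than 2x edge exclusion, "
                "zero countable region"
            )
            continue
        trees.setdefault((g.contig, g.strand), IntervalTree()).addi(lo, hi, g.gene_id)

    samples = list(sample_ids) if sample_ids is not None else sorted(
        {a.sample_id for a in alignments}
    )
    gene_ids = [g.gene_id for g in genes]
    counts = pd.DataFrame(0, index=gene_ids, columns=samples, dtype=np.int64)
    dropped_ambiguous = 0
    for a in alignments:
        tree = trees.get((a.contig, a.strand))
        if tree is None:
            continue
        hits = tree[five_prime_index(a)]
        if not hits:
            continue
        if len(hits) > 1:
            dropped_ambiguous += 1
            continue
        gene_id = next(iter(hits)).data
        if a.sample_id in counts.columns:
            counts.at[gene_id, a.sample_id] += 1
    if dropped_ambiguous:
        logger.info(
            "dropped %d reads overlapping multiple countable windows",
            dropped_ambiguous,
        )
    return ExpressionTable(counts=counts, feature_kind="gene")


def compute_rpm(table: ExpressionTable) -> ExpressionTable:
    """Populate rpm = counts / per-sample denominator * 1e6.

    The denominator is the per-sample sum of feature counts. In gene mode the
    reporting mask hides features with <= ``min_reads_report`` reads; primer
    mode reports every primer. A zero denominator flags the sample and leaves
    its rpm undefined (NaN), never a silent zero.
    """
    counts = table.counts
    denom = counts.sum(axis=0).astype(float)
    flagged = [s for s in counts.columns if denom[s] == 0]
    denom_safe = denom.replace(0, np.nan)
    rpm = counts.div(denom_safe, axis=1) * 1e6
    if table.feature_kind == "gene":
        rpm = rpm.where(counts > table.min_reads_report)
    table.rpm = rpm
    table.flagged_samples = flagged
    return table


# ---------------------------------------------------------------------------
# Primer-level assignment and expression
# ---------------------------------------------------------------------------


def _priming_locations(pool: PrimerPool) -> dict[tuple[str, str], tuple[np.ndarray, list[str]]]:
    locs: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for p in pool.primers:
        locs.setdefault((p.contig, p.target_strand), []).append(
            (p.match_coordinate, p.primer_id)
        )
    out = {}
    for key, pairs in locs.items():
        pairs.sort()
        out[key] = (np.array([c for c, _ in pairs]), [pid for _, pid in pairs])
    return out


def assign_to_primers(
    alignments: Sequence[AdjustedAlignment],
    pool: PrimerPool,
    tolerance: int = 0,
) -> list[PrimerAssignment]:
    """Assign each read to the nearest priming location within ``tolerance``.

    The read's strand must match the orientation of the second-strand read
    the primer produces (the target strand). Exact distance ties between two
    primers leave the read UNASSIGNED with a tie flag.
    """
    locs = _priming_locations(pool)
    out: list[PrimerAssignment] = []
    for a in alignments:
        entry = locs.get((a.contig, a.strand))
        if entry is None:
            out.append(PrimerAssignment(a.read_id, a.sample_id, UNASSIGNED))
            continue
        coords, ids = entry
        i = int(np.searchsorted(coords, a.adj_pos))
        cands: list[tuple[int, int]] = []  # (abs distance, index)
        if i < len(coords):
            cands.append((abs(int(coords[i]) - a.adj_pos), i))
        if i > 0:
            cands.append((abs(int(coords[i - 1]) - a.adj_pos), i - 1))
        cands.sort()
        if not cands or cands[0][0] > tolerance:
            out.append(PrimerAssignment(a.read_id, a.sample_id, UNASSIGNED))
            continue
        if len(cands) > 1 and cands[0][0] == cands[1][0] and cands[0][1] != cands[1][1]:
            out.append(
                PrimerAssignment(a.read_id, a.sample_id, UNASSIGNED, tie=True)
            )
            continue
        best = cands[0][1]
        out.append(
            PrimerAssignment(
                a.read_id,
                a.sample_id,
                ids[best],
                match_offset=a.adj_pos - int(coords[best]),
            )
        )
    return out


def primer_expression(
    assignments: Sequence[PrimerAssignment],
    pool: PrimerPool,
    sample_ids: Optional[Sequence[str]] = None,
) -> ExpressionTable:
    """Per-primer counts and rpm, normalized per million primer-mapped reads."""
    samples = list(sample_ids) if sample_ids is not None else sorted(
        {a.sample_id for a in assignments}
    )
    primer_ids = [p.primer_id for p in pool.primers]
    counts = pd.DataFrame(0, index=primer_ids, columns=samples, dtype=np.int64)
    for a in assignments:
        if a.primer_id != UNASSIGNED and a.sample_id in counts.columns:
            counts.at[a.primer_id, a.sample_id] += 1
    table = ExpressionTable(
        counts=counts,
        feature_kind="primer",
        denominator_policy="primer_mapped_reads",
    )
    return compute_rpm(table)


def gene_expression_from_primers(
    primer_table: ExpressionTable, pool: PrimerPool
) -> ExpressionTable:
    """Gene expression as the median rpm over the gene's primers.

    Genes with no primer in the pool are absent. The median over an even
    number of primers is the mean of the middle two.
    """
    if primer_table.rpm is None:
        compute_rpm(primer_table)
    gene_of = {p.primer_id: p.gene_id for p in pool.primers}
    rpm = primer_table.rpm
    grouped = rpm.groupby(
        rpm.index.map(gene_of).rename("gene_id")
    ).median()
    counts = primer_table.counts.groupby(
        primer_table.counts.index.map(gene_of).rename("gene_id")
    ).sum()
    table = ExpressionTable(
        counts=counts.loc[grouped.index],
        feature_kind="gene",
        min_reads_report=primer_table.min_reads_report,
        denominator_policy=primer_table.denominator_policy,
    )
    table.rpm = grouped
    return table


# ---------------------------------------------------------------------------
# Mispriming classification
# ---------------------------------------------------------------------------


def classify_misprimes(
    unmapped: Sequence[SampleRead],
    genome: ReferenceGenome,
    pool: PrimerPool,
    head_len: int = 20,
    min_tail: int = 15,
    max_mismatches: int = 2,
    tolerance: int = 0,
) -> list[MisprimeEvent]:
    """Split-read identification of nonspecific priming among unmapped reads.

    Each read is split at ``head_len``; head and tail are mapped
    independently with the internal mapper. A read whose head maps to a
    priming location yields a MisprimeEvent; the event carries the adjusted
    location of the tail mapping when the tail is at least ``min_tail`` nt
    and maps, and is UNRESOLVED otherwise. Reads shorter than ``head_len``
    are skipped with a warning.
    """
    usable = []
    for r in unmapped:
        if len(r.sequence) < head_len:
            warnings.warn(f"read {r.read_id!r} shorter than head_len, skipped")
            continue
        usable.append(r)
    heads = [
        SampleRead(r.read_id, r.sample_id, r.sequence[:head_len], None)
        for r in usable
    ]
    head_aln, _ = map_reads(heads, genome, max_mismatches)
    head_adj = {a.read_id: a for a in adjust_positions(head_aln)}
    events: list[MisprimeEvent] = []
    by_id = {r.read_id: r for r in usable}
    assigned = assign_to_primers(
        [head_adj[rid] for rid in head_adj], pool, tolerance
    )
    for asg in assigned:
        if asg.primer_id == UNASSIGNED:
            continue
        read = by_id[asg.read_id]
        tail_seq = read.sequence[head_len:]
        if len(tail_seq) < min_tail:
            events.append(
                MisprimeEvent(read.read_id, read.sample_id, asg.primer_id, False)
            )
            continue
        tail = SampleRead(read.read_id, read.sample_id, tail_seq, None)
        tail_aln, _ = map_reads([tail], genome, max_mismatches)
        if not tail_aln:
            events.append(
                MisprimeEvent(read.read_id, read.sample_id, asg.primer_id, False)
            )
            continue
        t = adjust_positions(tail_aln)[0]
        events.append(
            MisprimeEvent(
                read.read_id,
                read.sample_id,
                asg.primer_id,
                True,
                misprime_contig=t.contig,
                misprime_strand=t.strand,
                misprime_pos=t.adj_pos,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Replicate agreement
# ---------------------------------------------------------------------------


def agreement_stats(
    table: ExpressionTable, min_reads: Optional[int] = None
) -> AgreementStats:
    """Pairwise Pearson r of log10 rpm and the median, across features, of
    the standard deviation of log2 rpm across samples.

    Features must exceed the reporting threshold in every sample (joint
    mask). Pairs sharing fewer than two features are flagged with r = NaN.
    """
    if table.counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    threshold = min_reads if min_reads is not None else table.min_reads_report
    counts = table.counts
    denom = counts.sum(axis=0).astype(float).replace(0, np.nan)
    rpm = counts.div(denom, axis=1) * 1e6
    mask = (counts > threshold).all(axis=1)
    rpm = rpm[mask]
    samples = list(counts.columns)
    r = pd.DataFrame(np.nan, index=samples, columns=samples, dtype=float)
    flagged = []
    log10 = np.log10(rpm)
    for a, b in itertools.combinations_with_replacement(samples, 2):
        if len(rpm) < 2:
            flagged.append((a, b))
            continue
        val = float(np.corrcoef(log10[a], log10[b])[0, 1])
        r.at[a, b] = val
        r.at[b, a] = val
    if len(rpm) >= 2:
        sd = np.log2(rpm).std(axis=1, ddof=1)
        median_sd = float(sd.median())
    else:
        median_sd = float("nan")
    return AgreementStats(
        pairwise_r=r,
        median_sd_log2fc=median_sd,
        n_features=int(mask.sum()),
        flagged_pairs=flagged,
    )
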
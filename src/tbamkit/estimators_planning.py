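"""Barcode-switching rate estimation and sequencing-depth redistribution.

Two estimators of sample crosstalk are provided. The knockout estimator uses
a deletion strain pooled with wild-type samples: any read of the deleted
feature carrying the knockout barcode must have switched in from one of the
wild-type samples, so dividing the knockout/WT count ratio by the number of
target-containing samples gives the switching rate between one specific pair
of samples. The mixed-species estimator pools two organisms and reports the
overall fraction of molecules carrying the wrong barcode (reads of species A
under a species-B barcode over all uniquely mapped species-A reads).

Redistribution planning quantifies how much sequencing is saved by capturing
genes of similar abundance in separate primer pools. For one pool, reaching
``min_reads`` on the least-abundant gene requires scaling the whole pool by
``min_reads / count_last``; splitting the descending-sorted gene list into
consecutive groups applies that factor per group, and the ratio of the
single-pool requirement to the summed per-group requirement is the fold
reduction in required depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass(frozen=True)
class SwitchEstimate:
    rate: float
    numerator_reads: int
    denominator_reads: int
    n_target_samples: int
    method: str  # knockout | mixed_species

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("negative rate")


@dataclass
class RedistributionPlan:
    groups: list[list[int]]  # indices into the descending-sorted count list
    per_group_required: list[int]
    total_required: int
    single_pool_required: int
    fold_reduction: float
    min_reads_per_gene: int = 100

    def __post_init__(self) -> None:
        if self.total_required != sum(self.per_group_required):
            raise ValueError("total_required != sum of per-group requirements")


def knockout_switch_rate(
    ko_reads: int, wt_reads: float, n_target_samples: int
) -> SwitchEstimate:
    """Per-sample-pair switching rate from a knockout-depletion experiment.

    rate = (ko_reads / wt_reads) / n_target_samples, i.e. the knockout/WT
    read ratio for the deleted feature spread over the samples that could
    have donated a switched read.
    """
    if wt_reads <= 0:
        raise ValueError("wt_reads must be positive; rate undefined")
    if n_target_samples < 1:
        raise ValueError("n_target_samples must be >= 1")
    if ko_reads < 0:
        raise ValueError("ko_reads must be >= 0")
    rate = (ko_reads / wt_reads) / n_target_samples
    return SwitchEstimate(
        rate=rate,
        numerator_reads=int(ko_reads),
        denominator_reads=int(round(wt_reads)),
        n_target_samples=n_target_samples,
        method="knockout",
    )


def cross_species_switch_rate(
    foreign_barcode_reads: int, total_unique_reads: int
) -> SwitchEstimate:
    """Overall switching rate from a mixed-species pool: reads of one species
    carrying the other species' barcode over all uniquely mapped reads of
    that species."""
    if total_unique_reads <= 0:
        raise ValueError("total_unique_reads must be positive; rate undefined")
    if foreign_barcode_reads < 0:
        raise ValueError("foreign_barcode_reads must be >= 0")
    return SwitchEstimate(
        rate=foreign_barcode_reads / total_unique_reads,
        numerator_reads=foreign_barcode_reads,
        denominator_reads=total_unique_reads,
        n_target_samples=1,
        method="mixed_species",
    )


def _validate_descending(counts: Sequence[float]) -> None:
    for c in counts:
        if c <= 0:
            raise ValueError(
                "all counts must be positive: a zero-count gene is "
                "unreachable at any depth"
            )
    for a, b in zip(counts, counts[1:]):
        if a < b:
            raise ValueError("counts must be sorted in descending order")


def required_reads_single_pool(
    counts: Sequence[float], min_reads: int = 100
) -> int:
    """Reads needed so the least-abundant gene reaches ``min_reads``:
    ceil(min_reads / counts[-1] * sum(counts))."""
    if len(counts) == 0:
        return 0
    _validate_descending(counts)
    factor = min_reads / counts[-1]
    return math.ceil(factor * sum(counts))


def plan_redistribution(
    counts: Sequence[float],
    n_groups: int,
    min_reads: int = 100,
) -> RedistributionPlan:
    """Partition descending-sorted counts into ``n_groups`` consecutive,
    near-equal blocks (sizes ceil(n/k) then floor(n/k), larger blocks first)
    and apply the single-pool requirement per block.

    fold_reduction = single-pool requirement / summed per-group requirement;
    it is >= 1 for any descending grouping, with equality when within-group
    skew everywhere matches the whole-set skew (e.g. uniform counts).
    """
    n = len(counts)
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups > n:
        raise ValueError("more groups than features")
    _validate_descending(counts)
    base, rem = divmod(n, n_groups)
    groups: list[list[int]] = []
    start = 0
    for g in range(n_groups):
        size = base + (1 if g < rem else 0)
        groups.append(list(range(start, start + size)))
        start += size
    per_group = [
        required_reads_single_pool([counts[i] for i in grp], min_reads)
        for grp in groups
    ]
    total = sum(per_group)
    single = required_reads_single_pool(counts, min_reads)
    return RedistributionPlan(
        groups=groups,
        per_group_required=per_group,
        total_required=total,
        single_pool_required=single,
        fold_reduction=single / total if total else float("nan"),
        min_reads_per_gene=min_reads,
    )
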
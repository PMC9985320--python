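"""Counting, primer assignment, mispriming, and replicate agreement."""

import numpy as np
import pandas as pd
import pytest

from tbamkit import (
    ExpressionTable,
    GeneModel,
    ReferenceGenome,
    SampleRead,
    agreement_stats,
    assign_to_primers,
    classify_misprimes,
    compute_rpm,
    count_gene_reads,
    gene_expression_from_primers,
    primer_expression,
)
from tbamkit.preprocess_align import AdjustedAlignment
from tbamkit.primer_design import PrimerCandidate, PrimerPool
from tbamkit.quantify import UNASSIGNED, PrimerAssignment
from tbamkit.reference_io import revcomp

from conftest import random_dna


def _adj(adj_pos, strand="+", contig="c1", rid="r", sid="s1", length=30):
    pos = adj_pos if strand == "+" else adj_pos - length
    return AdjustedAlignment(rid, sid, contig, strand, pos, length, 0)


def _primer(gene_id, start, end, strand="+", contig="c1", seq=None):
    seq = seq or "A" * (end - start)
    return PrimerCandidate(
        gene_id=gene_id, contig=contig, target_strand=strand,
        anneal_start=start, anneal_end=end, sequence=seq, tm=55.0,
        penalty=0.0, transcript_offset=start if strand == "+" else -end,
    )


# ---------------------------------------------------------------------------
# Gene counting
# ---------------------------------------------------------------------------


class TestCountGeneReads:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_edge_exclusion_on_200nt_cds(self, strand):
        gene = GeneModel("g", "c1", strand, 1000, 1200)
        offsets = [5, 35, 100, 169, 175]
        alns = []
        for i, off in enumerate(offsets):
            # transcript offset -> genomic 5' base -> adjusted coordinate
            g5 = 1000 + off if strand == "+" else 1200 - 1 - off
            adj = g5 if strand == "+" else g5 + 1
            alns.append(_adj(adj, strand, rid=f"r{i}"))
        table = count_gene_reads(alns, [gene])
        assert table.counts.at["g", "s1"] == 3  # offsets 35, 100, 169

    def test_strand_mismatch_not_counted(self):
        gene = GeneModel("g", "c1", "+", 0, 200)
        table = count_gene_reads([_adj(100, "-")], [gene])
        assert table.counts.at["g", "s1"] == 0

    def test_zero_alignments_all_zero(self):
        gene = GeneModel("g", "c1", "+", 0, 200)
        table = count_gene_reads([], [gene], sample_ids=["s1"])
        assert (table.counts.values == 0).all()

    def test_short_cds_warns_zero_countable(self):
        gene = GeneModel("tiny", "c1", "+", 0, 50)
        with pytest.warns(UserWarning, match="zero countable"):
            table = count_gene_reads([_adj(25)], [gene])
        assert table.counts.at["tiny", "s1"] == 0

    def test_ambiguous_overlap_dropped(self):
        g1 = GeneModel("g1", "c1", "+", 0, 200)
        g2 = GeneModel("g2", "c1", "+", 50, 260)
        table = count_gene_reads([_adj(100)], [g1, g2])
        assert table.counts.values.sum() == 0


class TestComputeRpm:
    def test_single_gene_gets_one_million(self):
        counts = pd.DataFrame({"s1": [500]}, index=["g1"])
        table = compute_rpm(ExpressionTable(counts))
        assert table.rpm.at["g1", "s1"] == pytest.approx(1e6)

    def test_threshold_is_strictly_greater_than(self):
        counts = pd.DataFrame({"s1": [100, 101, 5000]},
                              index=["at", "above", "big"])
        table = compute_rpm(ExpressionTable(counts))
        assert np.isnan(table.rpm.at["at", "s1"])
        assert not np.isnan(table.rpm.at["above", "s1"])

    def test_reported_mass_bounded_by_one_million(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(30, 3)),
            index=[f"g{i}" for i in range(30)], columns=list("abc"),
        )
        table = compute_rpm(ExpressionTable(counts))
        total = table.rpm.fillna(0).sum(axis=0)
        assert (total <= 1e6 + 1e-6).all()
        # equality iff every counted feature passes the threshold
        all_pass = pd.DataFrame({"a": [200, 300], "b": [400, 500]},
                                index=["g1", "g2"])
        t2 = compute_rpm(ExpressionTable(all_pass))
        assert t2.rpm.sum(axis=0).values == pytest.approx([1e6, 1e6])

    def test_zero_denominator_flagged_not_silent_zero(self):
        counts = pd.DataFrame({"ok": [300], "empty": [0]}, index=["g"])
        table = compute_rpm(ExpressionTable(counts))
        assert table.flagged_samples == ["empty"]
        assert np.isnan(table.rpm.at["g", "empty"])

    def test_rpm_invariant_under_scaling_one_sample(self):
        counts = pd.DataFrame({"s1": [200, 400, 800]}, index=list("xyz"))
        t1 = compute_rpm(ExpressionTable(counts))
        t2 = compute_rpm(ExpressionTable(counts * 7))
        pd.testing.assert_frame_equal(t1.rpm, t2.rpm)


# ---------------------------------------------------------------------------
# Primer assignment and expression
# ---------------------------------------------------------------------------


class TestAssignToPrimers:
    def setup_method(self):
        self.pool = PrimerPool([
            _primer("gA", 100, 120, "+"),
            _primer("gB", 500, 520, "-"),
        ])

    def test_exact_match_offset_zero(self):
        asg = assign_to_primers([_adj(100, "+")], self.pool)
        assert asg[0].primer_id == "gA:100-120(+)"
        assert asg[0].match_offset == 0

    def test_reverse_target_matches_at_anneal_end(self):
        asg = assign_to_primers([_adj(520, "-")], self.pool)
        assert asg[0].primer_id == "gB:500-520(-)"

    def test_no_primer_within_tolerance_unassigned(self):
        asg = assign_to_primers([_adj(300, "+")], self.pool)
        assert asg[0].primer_id == UNASSIGNED

    def test_tolerance_zero_vs_one_on_one_off_read(self):
        strict = assign_to_primers([_adj(101, "+")], self.pool, tolerance=0)
        loose = assign_to_primers([_adj(101, "+")], self.pool, tolerance=1)
        assert strict[0].primer_id == UNASSIGNED
        assert loose[0].primer_id == "gA:100-120(+)"
        assert loose[0].match_offset == 1

    def test_equidistant_tie_flagged_unassigned(self):
        pool = PrimerPool([_primer("gA", 100, 120), _primer("gA", 104, 124)])
        asg = assign_to_primers([_adj(102, "+")], pool, tolerance=2)
        assert asg[0].primer_id == UNASSIGNED and asg[0].tie

    def test_wrong_strand_never_assigned(self):
        asg = assign_to_primers([_adj(100, "-")], self.pool, tolerance=0)
        assert asg[0].primer_id == UNASSIGNED

    def test_conservation_assigned_plus_unassigned(self):
        alns = [_adj(100), _adj(300), _adj(520, "-"), _adj(101)]
        asg = assign_to_primers(alns, self.pool)
        assert len(asg) == len(alns)


class TestPrimerExpression:
    def test_rpm_arithmetic_10_20_30(self):
        pool = PrimerPool([_primer("g", 0, 20), _primer("g", 50, 70),
                           _primer("g", 100, 120)])
        ids = [p.primer_id for p in pool.primers]
        assignments = (
            [PrimerAssignment(f"a{i}", "s1", ids[0]) for i in range(10)]
            + [PrimerAssignment(f"b{i}", "s1", ids[1]) for i in range(20)]
            + [PrimerAssignment(f"c{i}", "s1", ids[2]) for i in range(30)]
        )
        table = primer_expression(assignments, pool)
        got = table.rpm["s1"].tolist()
        assert got == pytest.approx(
            [10 / 60 * 1e6, 20 / 60 * 1e6, 30 / 60 * 1e6]
        )
        assert table.rpm["s1"].sum() == pytest.approx(1e6)

    def test_single_primer_takes_all(self):
        pool = PrimerPool([_primer("g", 0, 20)])
        pid = pool.primers[0].primer_id
        table = primer_expression(
            [PrimerAssignment(f"r{i}", "s1", pid) for i in range(5)], pool
        )
        assert table.rpm.at[pid, "s1"] == pytest.approx(1e6)

    def test_sample_with_zero_assigned_flagged(self):
        pool = PrimerPool([_primer("g", 0, 20)])
        pid = pool.primers[0].primer_id
        table = primer_expression(
            [PrimerAssignment("r0", "s1", pid),
             PrimerAssignment("r1", "s2", UNASSIGNED)],
            pool, sample_ids=["s1", "s2"],
        )
        assert table.flagged_samples == ["s2"]


class TestGeneExpressionFromPrimers:
    def _table(self, rpms, gene="g"):
        pool = PrimerPool([
            _primer(gene, 100 * i, 100 * i + 20) for i in range(len(rpms))
        ])
        counts = pd.DataFrame(
            {"s1": [max(1, int(r / 10)) for r in rpms]},
            index=[p.primer_id for p in pool.primers],
        )
        table = ExpressionTable(counts, feature_kind="primer")
        table.rpm = pd.DataFrame({"s1": rpms}, index=counts.index)
        return table, pool

    def test_median_of_one(self):
        table, pool = self._table([777.0])
        out = gene_expression_from_primers(table, pool)
        assert out.rpm.at["g", "s1"] == pytest.approx(777.0)

    def test_median_of_three(self):
        table, pool = self._table([100.0, 400.0, 10000.0])
        out = gene_expression_from_primers(table, pool)
        assert out.rpm.at["g", "s1"] == pytest.approx(400.0)

    def test_even_count_mean_of_middle_two(self):
        table, pool = self._table([10.0, 20.0, 30.0, 40.0])
        out = gene_expression_from_primers(table, pool)
        assert out.rpm.at["g", "s1"] == pytest.approx(25.0)

    def test_outlier_primer_does_not_move_median(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(900, 1100, size=11).tolist()  # lacZ-style tiling
        rpms = base + [10_000.0]  # one 10x outlier
        table, pool = self._table(rpms)
        out = gene_expression_from_primers(table, pool)
        assert 900 <= out.rpm.at["g", "s1"] <= 1100
        assert out.rpm.at["g", "s1"] == pytest.approx(
            float(np.median(rpms)), rel=1e-12
        )


# ---------------------------------------------------------------------------
# Mispriming
# ---------------------------------------------------------------------------


class TestClassifyMisprimes:
    @pytest.fixture()
    def world(self):
        rng = np.random.default_rng(13)
        genome = ReferenceGenome({"c1": random_dna(rng, 4000)})
        primer_seq = genome.contigs["c1"][1000:1020]
        pool = PrimerPool([
            _primer("gT", 1000, 1020, "+", seq=primer_seq)
        ])
        return genome, pool

    def test_head_mapping_nowhere_yields_no_event(self, world):
        genome, pool = world
        rng = np.random.default_rng(99)
        read = SampleRead("r", "s", random_dna(rng, 50), None)
        assert classify_misprimes([read], genome, pool) == []

    def test_chimera_resolved_to_off_target_locus(self, world):
        genome, pool = world
        body = genome.contigs["c1"][3000:3030]
        read = SampleRead("r", "s", genome.contigs["c1"][1000:1020] + body, None)
        events = classify_misprimes([read], genome, pool)
        assert len(events) == 1
        e = events[0]
        assert e.resolved
        assert (e.misprime_contig, e.misprime_strand, e.misprime_pos) == (
            "c1", "+", 3000,
        )
        assert e.primer_id == pool.primers[0].primer_id

    def test_short_tail_is_unresolved(self, world):
        genome, pool = world
        body = genome.contigs["c1"][3000:3010]  # 10 nt < min_tail
        read = SampleRead("r", "s", genome.contigs["c1"][1000:1020] + body, None)
        events = classify_misprimes([read], genome, pool)
        assert len(events) == 1 and not events[0].resolved
        assert events[0].misprime_pos is None

    def test_read_shorter_than_head_skipped_with_warning(self, world):
        genome, pool = world
        read = SampleRead("r", "s", "ACGTACGT", None)
        with pytest.warns(UserWarning, match="shorter than head_len"):
            events = classify_misprimes([read], genome, pool)
        assert events == []


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------


class TestAgreementStats:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            {"s1": rng.integers(150, 5000, 40)}, index=range(40)
        )
        counts["s2"] = counts["s1"]
        stats = agreement_stats(ExpressionTable(counts))
        assert stats.pairwise_r.at["s1", "s2"] == pytest.approx(1.0)

    def test_scaled_sample_still_r_one(self):
        rng = np.random.default_rng(6)
        base = rng.integers(150, 5000, 40)
        counts = pd.DataFrame({"s1": base, "s2": base * 3}, index=range(40))
        stats = agreement_stats(ExpressionTable(counts))
        # depth scaling is a log-space shift: correlation unchanged
        assert stats.pairwise_r.at["s1", "s2"] == pytest.approx(1.0)

    def test_median_sd_recovers_planted_log2_noise(self):
        rng = np.random.default_rng(8)
        sigma_log2 = 0.25
        n_genes, n_samples = 200, 12
        base = rng.uniform(1000, 50_000, n_genes)
        noise = rng.normal(0.0, sigma_log2, size=(n_genes, n_samples))
        counts = pd.DataFrame(
            np.rint(base[:, None] * 2.0 ** noise).astype(int),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        stats = agreement_stats(ExpressionTable(counts))
        # direct resampling oracle on the same table
        denom = counts.sum(axis=0).astype(float)
        rpm = counts / denom * 1e6
        mask = (counts > 100).all(axis=1)
        direct = float(np.log2(rpm[mask]).std(axis=1, ddof=1).median())
        assert stats.median_sd_log2fc == pytest.approx(direct, rel=1e-12)
        assert stats.median_sd_log2fc == pytest.approx(sigma_log2, rel=0.15)

    def test_too_few_shared_features_flagged(self):
        counts = pd.DataFrame({"s1": [5, 5000], "s2": [5000, 5]},
                              index=["g1", "g2"])
        stats = agreement_stats(ExpressionTable(counts))
        assert stats.flagged_pairs  # no feature passes in both samples
        assert np.isnan(stats.median_sd_log2fc)
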
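import io

import pytest

from crossreg.conservation import (
    ChainAlignment,
    ChainParseError,
    LiftStatus,
    classify_functionally_conserved,
    liftover,
    mean_conservation_score,
    parse_chain,
    read_bedgraph,
    read_wig,
    write_chain,
    ConservationTrack,
)
from crossreg.core_intervals import GenomicInterval, PeakSet


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


IDENTITY = ChainAlignment(
    score=1_000, t_name="chr1", t_size=10_000, t_strand="+",
    t_start=0, t_end=10_000, q_name="chr1", q_size=10_000, q_strand="+",
    q_start=0, q_end=10_000, chain_id="1", blocks=[(10_000, 0, 0)],
)


class TestParseChain:
    CHAIN_TEXT = (
        "chain 4900 chr1 1000 + 0 250 chrQ 800 + 100 300 7\n"
        "100 50 0\n"
        "100\n"
        "\n"
    )

    def test_block_arithmetic_verified(self):
        (chain,) = parse_chain(io.StringIO(self.CHAIN_TEXT))
        assert chain.blocks == [(100, 50, 0), (100, 0, 0)]
        assert chain.t_end - chain.t_start == 250
        assert chain.q_end - chain.q_start == 200

    def test_arithmetic_violation_raises(self):
        bad = self.CHAIN_TEXT.replace("chain 4900 chr1 1000 + 0 250",
                                      "chain 4900 chr1 1000 + 0 260")
        with pytest.raises(ChainParseError, match="chain 7"):
            parse_chain(io.StringIO(bad))

    def test_malformed_block_names_line(self):
        bad = "chain 1 chr1 100 + 0 10 chrQ 100 + 0 10 3\n10 x\n\n"
        with pytest.raises(ChainParseError, match="chain 3"):
            parse_chain(io.StringIO(bad))

    def test_roundtrip_through_writer(self, tmp_path):
        chains = parse_chain(io.StringIO(self.CHAIN_TEXT))
        path = tmp_path / "x.chain"
        write_chain(path, chains)
        again = parse_chain(path)
        assert again == chains


class TestLiftover:
    def test_identity_chain_is_identity(self):
        import numpy as np
        rng = np.random.default_rng(0)
        for _ in range(50):
            start = int(rng.integers(0, 9_000))
            end = start + int(rng.integers(1, 1_000))
            res = liftover(iv("chr1", start, end), [IDENTITY])
            assert res.status is LiftStatus.MAPPED
            assert (res.mapped_interval.start, res.mapped_interval.end) == (start, end)
            assert res.match_fraction == 1.0

    def test_low_match_rejected(self):
        # only 150 of 1,000 bases inside aligned blocks
        chain = ChainAlignment(
            score=100, t_name="chr1", t_size=10_000, t_strand="+",
            t_start=0, t_end=1_000, q_name="chrQ", q_size=10_000, q_strand="+",
            q_start=0, q_end=150, chain_id="1", blocks=[(150, 850, 0)],
        )
        res = liftover(iv("chr1", 0, 1_000), [chain], min_match=0.2)
        assert res.status is LiftStatus.UNMAPPED_LOW_MATCH
        assert res.match_fraction == pytest.approx(0.15)

    def test_no_chain(self):
        res = liftover(iv("chr9", 0, 100), [IDENTITY])
        assert res.status is LiftStatus.UNMAPPED_NO_CHAIN

    def test_minus_strand_reflection(self):
        # target [100, 200) aligns to query alignment coords [100, 200) on
        # '-' of a 10,000 bp chromosome -> genome coords [9,800, 9,900)
        chain = ChainAlignment(
            score=100, t_name="chr1", t_size=10_000, t_strand="+",
            t_start=0, t_end=1_000, q_name="chrQ", q_size=10_000, q_strand="-",
            q_start=0, q_end=1_000, chain_id="1", blocks=[(1_000, 0, 0)],
        )
        res = liftover(iv("chr1", 100, 200), [chain])
        assert res.status is LiftStatus.MAPPED
        assert (res.mapped_interval.start, res.mapped_interval.end) == (9_800, 9_900)

    def test_ambiguous_two_disjoint_chains(self):
        other = ChainAlignment(
            score=500, t_name="chr1", t_size=10_000, t_strand="+",
            t_start=0, t_end=10_000, q_name="chr5", q_size=50_000, q_strand="+",
            q_start=40_000, q_end=50_000, chain_id="2", blocks=[(10_000, 0, 0)],
        )
        res = liftover(iv("chr1", 100, 200), [IDENTITY, other])
        assert res.status is LiftStatus.AMBIGUOUS

    def test_round_trip_containment(self):
        forward = ChainAlignment(
            score=10, t_name="chr1", t_size=10_000, t_strand="+",
            t_start=1_000, t_end=2_050, q_name="chrQ", q_size=10_000, q_strand="+",
            q_start=500, q_end=1_550, chain_id="1",
            blocks=[(500, 50, 50), (500, 0, 0)],
        )
        inverse = ChainAlignment(
            score=10, t_name="chrQ", t_size=10_000, t_strand="+",
            t_start=500, t_end=1_550, q_name="chr1", q_size=10_000, q_strand="+",
            q_start=1_000, q_end=2_050, chain_id="1",
            blocks=[(500, 50, 50), (500, 0, 0)],
        )
        original = iv("chr1", 1_200, 1_900)
        there = liftover(original, [forward])
        assert there.status is LiftStatus.MAPPED
        back = liftover(there.mapped_interval, [inverse])
        assert back.status is LiftStatus.MAPPED
        assert back.mapped_interval.start <= original.start
        assert back.mapped_interval.end >= original.end

    def test_match_fraction_monotone_in_gap_width(self):
        fractions = []
        for gap in (0, 100, 200, 400):
            chain = ChainAlignment(
                score=10, t_name="chr1", t_size=10_000, t_strand="+",
                t_start=0, t_end=1_000 + gap, q_name="chrQ", q_size=10_000,
                q_strand="+", q_start=0, q_end=1_000, chain_id="1",
                blocks=[(500, gap, 0), (500, 0, 0)],
            )
            res = liftover(iv("chr1", 0, 1_000), [chain], min_match=0.01)
            fractions.append(res.match_fraction)
        assert fractions == sorted(fractions, reverse=True)

    def test_bad_min_match(self):
        with pytest.raises(ValueError):
            liftover(iv("chr1", 0, 100), [IDENTITY], min_match=0.0)


class TestClassifyConserved:
    def test_three_way_overlap(self):
        focal = PeakSet([iv("chr1", 100, 200)])
        ref = PeakSet([iv("chr1", 150, 250)])
        other = PeakSet([iv("chr1", 180, 300)])
        labels, counts = classify_functionally_conserved(focal, ref, other)
        assert labels == [True]
        assert (counts.n_conserved, counts.n_total) == (1, 1)

    def test_reference_only_not_conserved(self):
        focal = PeakSet([iv("chr1", 100, 200)])
        ref = PeakSet([iv("chr1", 150, 250)])
        other = PeakSet([iv("chr1", 5_000, 5_100)])
        labels, _ = classify_functionally_conserved(focal, ref, other)
        assert labels == [False]

    def test_unmapped_counted_in_total(self):
        focal = PeakSet([iv("chr1", 100, 200)])
        ref = PeakSet([iv("chr1", 100, 200)])
        other = PeakSet([iv("chr1", 100, 200)])
        _, counts = classify_functionally_conserved(focal, ref, other, n_unmapped=3)
        assert counts.n_total == 4
        assert counts.fraction == pytest.approx(0.25)

    def test_frame_mismatch_detected(self):
        focal = PeakSet([iv("chrA_1", 0, 100)])
        ref = PeakSet([iv("chr1", 0, 100)])
        with pytest.raises(ValueError, match="coordinate frame"):
            classify_functionally_conserved(focal, ref, PeakSet([]))

    def test_midpoint_distance_mode(self):
        focal = PeakSet([iv("chr1", 0, 1_000)])       # midpoint 500
        ref = PeakSet([iv("chr1", 2_000, 3_000)])     # midpoint 2,500
        other = PeakSet([iv("chr1", 1_900, 2_900)])
        labels0, _ = classify_functionally_conserved(focal, ref, other, 0)
        assert labels0 == [False]
        labels_d, _ = classify_functionally_conserved(focal, ref, other, 2_000)
        assert labels_d == [True]


class TestScores:
    def test_constant_track(self):
        track = ConservationTrack({"chr1": [(0, 1_000, 0.8)]})
        mean, cov = mean_conservation_score(iv("chr1", 100, 200), track)
        assert mean == pytest.approx(0.8)
        assert cov == 1.0

    def test_half_and_half(self):
        track = ConservationTrack({"chr1": [(0, 500, 1.0), (500, 1_000, 0.0)]})
        mean, cov = mean_conservation_score(iv("chr1", 0, 1_000), track)
        assert mean == pytest.approx(0.5)

    def test_no_data_is_undefined(self):
        track = ConservationTrack({"chr1": [(0, 100, 0.5)]})
        mean, cov = mean_conservation_score(iv("chr1", 5_000, 6_000), track)
        assert mean is None and cov == 0.0

    def test_score_range_enforced(self):
        with pytest.raises(ValueError):
            ConservationTrack({"chr1": [(0, 10, 1.5)]})

    def test_fixedstep_reader(self, tmp_path):
        p = tmp_path / "x.wig"
        p.write_text(
            "fixedStep chrom=chr1 start=11 step=1 span=1\n0.5\n0.7\n"
            "fixedStep chrom=chr1 start=101 step=50 span=50\n0.9\n"
        )
        track = read_wig(p)
        mean, _ = mean_conservation_score(iv("chr1", 10, 12), track)
        assert mean == pytest.approx(0.6)
        mean2, cov2 = mean_conservation_score(iv("chr1", 100, 150), track)
        assert mean2 == pytest.approx(0.9) and cov2 == 1.0

    def test_bedgraph_reader(self, tmp_path):
        p = tmp_path / "x.bedgraph"
        p.write_text("chr1\t0\t100\t0.25\nchr1\t100\t200\t0.75\n")
        track = read_bedgraph(p)
        mean, _ = mean_conservation_score(iv("chr1", 0, 200), track)
        assert mean == pytest.approx(0.5)
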
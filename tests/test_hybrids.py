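import numpy as np
import pandas as pd
import pytest

from ms2drs import (
    chain_and_call,
    classify_event,
    detect_hybrids,
    find_segments,
    hybrid_summary,
    revcomp,
    simulate_hybrids,
    simulate_reads,
)
from ms2drs.core_io import AlignedRead
from ms2drs.hybrids import AlignSegment, segments_from_sam_records
from ms2drs.synthetic import SimConfig

from _sw_oracle import oracle_segments, segments_agree


def _seg(qs, qe, rs, re_, strand="+", score=None):
    return AlignSegment(query_start=qs, query_end=qe, ref_start=rs, ref_end=re_,
                        strand=strand, score=score if score is not None else qe - qs)


class TestFindSegments:
    def test_exact_plus_strand_match(self, genome):
        segs = find_segments(genome.sequence[100:400], genome)
        assert len(segs) == 1
        s = segs[0]
        assert (s.query_start, s.query_end) == (0, 300)
        assert (s.ref_start, s.ref_end, s.strand) == (100, 400, "+")
        assert s.score == 300

    def test_exact_minus_strand_match(self, genome):
        segs = find_segments(revcomp(genome.sequence[100:400]), genome)
        assert len(segs) == 1
        assert (segs[0].ref_start, segs[0].ref_end, segs[0].strand) == (100, 400, "-")

    def test_deletion_read_two_segments(self, genome):
        read = genome.sequence[100:300] + genome.sequence[350:550]
        segs = find_segments(read, genome)
        assert len(segs) == 2
        a, b = segs
        assert (a.ref_start, a.ref_end) == (100, 300)
        assert (b.ref_start, b.ref_end) == (350, 550)
        assert b.query_start - a.query_end == 0  # query-adjacent

    def test_short_read_empty(self, genome):
        assert find_segments("ACGT" * 10, genome) == []

    @pytest.mark.parametrize("seed", [11, 12])
    def test_matches_dp_oracle_on_random_reads(self, genome, seed):
        """Production segments equal the exhaustive Smith-Waterman oracle."""
        rng = np.random.default_rng(seed)
        agree = 0
        n = 10
        for _ in range(n):
            length = int(rng.integers(80, 201))
            s = int(rng.integers(0, genome.length - length))
            read = genome.sequence[s:s + length]
            if rng.random() < 0.5:
                read = revcomp(read)
            read = "".join(b if rng.random() > 0.02 else "ACGT"[int(rng.integers(0, 4))]
                           for b in read)
            if segments_agree(find_segments(read, genome),
                              oracle_segments(read, genome.sequence)):
                agree += 1
        assert agree >= n - 1


class TestChainAndCall:
    def test_single_segment_is_not_hybrid(self):
        assert chain_and_call("r", [_seg(0, 200, 100, 300)]) is None

    def test_pos_pos_deletion(self):
        call = chain_and_call("r", [_seg(0, 200, 100, 300), _seg(200, 400, 330, 530)])
        assert call.junction_type == "pos_pos"
        assert call.event == "deletion" and call.delta == 30
        assert call.in_recombination_range
        assert call.junction_ref_positions == (300, 331)

    def test_foldback_overlapping_opposite_strands(self):
        call = chain_and_call("r", [_seg(0, 200, 100, 300, "+"),
                                    _seg(200, 380, 110, 290, "-")])
        assert call.junction_type == "foldback"
        assert call.event == "none"

    def test_strand_switch_distinct_loci(self):
        call = chain_and_call("r", [_seg(0, 200, 2000, 2200, "-"),
                                    _seg(200, 400, 100, 300, "+")])
        assert call.junction_type == "neg_pos"

    def test_same_locus_twice_is_not_hybrid(self):
        # two segments covering the same interval on the same strand
        call = chain_and_call("r", [_seg(0, 200, 100, 300), _seg(210, 400, 105, 295)])
        assert call is None

    def test_non_adjacent_segments_not_chained(self):
        call = chain_and_call("r", [_seg(0, 200, 100, 300), _seg(300, 500, 900, 1100)],
                              query_gap_tol=20)
        assert call is None


class TestClassifyEvent:
    def test_deletion(self):
        ev, d = classify_event(_seg(0, 200, 100, 300), _seg(200, 370, 330, 500))
        assert (ev, d) == ("deletion", 30)

    def test_duplication(self):
        ev, d = classify_event(_seg(0, 200, 100, 300), _seg(200, 440, 260, 500))
        assert (ev, d) == ("duplication", -40)

    def test_contiguous_is_no_event(self):
        ev, d = classify_event(_seg(0, 200, 100, 300), _seg(200, 400, 300, 500))
        assert (ev, d) == ("none", 0)

    def test_opposite_strands_rejected(self):
        with pytest.raises(ValueError, match="foldback"):
            classify_event(_seg(0, 200, 100, 300, "+"), _seg(200, 400, 330, 530, "-"))

    def test_simulated_neg_neg_duplication_recovered(self, genome):
        seqs, _, truth = simulate_hybrids(
            genome, [("neg_neg_duplication", 10, (45, 45))], seed=2, error_rate=0.02)
        calls = detect_hybrids(seqs, genome)
        got = {c.read_id: c for c in calls}
        hits = 0
        for _, row in truth.iterrows():
            c = got.get(row.read_id)
            if c and c.event == "duplication" and abs(abs(c.delta) - 45) <= 5:
                hits += 1
        assert hits >= 9


class TestEndToEnd:
    def test_error_free_non_hybrids_never_called(self, genome):
        cfg = SimConfig(seed=9, n_reads=200, error_rate=0.0)
        _, seqs, _, _ = simulate_reads(genome, cfg)
        assert detect_hybrids(seqs, genome) == []

    def test_foldbacks_never_typed_as_indel_event(self, genome):
        seqs, _, _ = simulate_hybrids(genome, [("foldback", 20, None)],
                                      seed=5, error_rate=0.02)
        calls = detect_hybrids(seqs, genome)
        assert len(calls) >= 19
        assert all(c.event == "none" for c in calls)
        assert all(c.junction_type == "foldback" for c in calls)

    def test_planted_hybrid_ratio_recovered(self, genome):
        n_hyb, n_plain = 50, 950
        seqs, _, _ = simulate_hybrids(genome, [("pos_pos_deletion", n_hyb, (20, 60))],
                                      seed=6, error_rate=0.02)
        _, plain, _, _ = simulate_reads(genome, SimConfig(seed=7, n_reads=n_plain,
                                                          error_rate=0.02))
        seqs.update(plain)
        calls = detect_hybrids(seqs, genome)
        ratio = len(calls) / len(seqs)
        assert ratio == pytest.approx(n_hyb / (n_hyb + n_plain), abs=0.01)


class TestHybridSummary:
    def _reads(self, n, timepoint="6h", strand="+"):
        return [AlignedRead(read_id=f"t{i}", strand=strand, ref_start=0, ref_end=100,
                            query_length=100, timepoint=timepoint) for i in range(n)]

    def test_simple_ratio(self):
        calls = [chain_and_call("r", [_seg(0, 200, 100, 300), _seg(200, 400, 330, 530)],
                                timepoint="6h") for _ in range(2)]
        summary, breakdown = hybrid_summary(calls, self._reads(1000))
        assert summary.ratio.iloc[0] == pytest.approx(0.002)
        assert breakdown["count"].sum() == 2

    def test_empty_calls_zero_ratio(self):
        summary, _ = hybrid_summary([], self._reads(100))
        assert (summary.ratio == 0).all()


class TestSamSegments:
    def test_supplementary_split_recovered(self, genome, tmp_path):
        import pysam

        sam = tmp_path / "split.sam"
        seq1, seq2 = genome.sequence[100:300], genome.sequence[350:550]
        with open(sam, "w") as fh:
            fh.write(f"@HD\tVN:1.6\n@SQ\tSN:{genome.name}\tLN:{genome.length}\n")
            fh.write(f"h1\t0\t{genome.name}\t101\t60\t200M200S\t*\t0\t0\t"
                     f"{seq1 + seq2}\t*\n")
            fh.write(f"h1\t2048\t{genome.name}\t351\t60\t200S200M\t*\t0\t0\t"
                     f"{seq1 + seq2}\t*\n")
        with pysam.AlignmentFile(str(sam), check_sq=False) as fh:
            by_read = segments_from_sam_records(fh)
        segs = sorted(by_read["h1"], key=lambda s: s.query_start)
        assert [(s.query_start, s.query_end, s.ref_start, s.ref_end) for s in segs] == \
            [(0, 200, 100, 300), (200, 400, 350, 550)]
        call = chain_and_call("h1", segs)
        assert call.event == "deletion" and call.delta == 50
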
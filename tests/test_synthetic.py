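import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from ms2drs import make_genome, revcomp, simulate_hybrids, simulate_modifications, simulate_reads
from ms2drs.core_io import AlignedRead
from ms2drs.synthetic import AG_HEXAMER, SimConfig, _STOPS


class TestMakeGenome:
    def test_default_layout(self, genome):
        assert genome.length == 3569
        assert len(genome.orfs) == 4
        for orf in genome.orfs:
            assert genome.sequence[orf.start:orf.start + 3] == "ATG"
            assert genome.sequence[orf.end - 3:orf.end] in _STOPS

    def test_ag_hexamer_planted_upstream(self, genome):
        for orf in genome.orfs:
            upstream = genome.sequence[max(0, orf.start - 20):orf.start]
            assert AG_HEXAMER in upstream

    def test_deterministic(self):
        assert make_genome(seed=3).sequence == make_genome(seed=3).sequence
        assert make_genome(seed=3).sequence != make_genome(seed=4).sequence

    def test_toy_layout(self):
        g = make_genome(length=1000, orf_layout={"orf1": (100, 400)}, seed=0)
        assert g.length == 1000 and len(g.orfs) == 1

    def test_bad_layout_rejected(self):
        with pytest.raises(ValueError):
            make_genome(length=1000, orf_layout={"big": (100, 2000)})


class TestSimulateReads:
    def test_pure_full_length(self, genome):
        cfg = SimConfig(seed=1, n_reads=50, class_mixture={"full_length": 1.0})
        reads, _, _, truth = simulate_reads(genome, cfg)
        assert len(reads) == 50
        assert all(r.span >= 0.93 * genome.length for r in reads)

    def test_pure_coat_subgenomic(self, genome):
        cfg = SimConfig(seed=1, n_reads=20, class_mixture={"coat_subgenomic": 1.0})
        reads, _, _, _ = simulate_reads(genome, cfg)
        coat = genome.orf("coat")
        for r in reads:
            assert r.ref_start <= coat.start and r.ref_end >= coat.end
            assert r.span < 800

    def test_error_free_reads_are_genome_substrings(self, genome):
        cfg = SimConfig(seed=2, n_reads=100, error_rate=0.0,
                        class_mixture={"full_length": 0.3, "five_prime_anchored": 0.3,
                                       "negative_full_length": 0.4})
        reads, seqs, _, _ = simulate_reads(genome, cfg)
        for r in reads:
            s = seqs[r.read_id]
            if r.strand == "-":
                s = revcomp(s)
            assert s == genome.sequence[r.ref_start:r.ref_end]

    def test_deterministic_truth(self, genome):
        cfg = SimConfig(seed=5, n_reads=100)
        t1 = simulate_reads(genome, cfg)[3]
        t2 = simulate_reads(genome, SimConfig(seed=5, n_reads=100))[3]
        pd.testing.assert_frame_equal(t1, t2)

    def test_mixture_must_sum_to_one(self, genome):
        cfg = SimConfig(class_mixture={"full_length": 0.5})
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_reads(genome, cfg)

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_class_counts_follow_mixture(self, genome, seed):
        """Multinomial goodness-of-fit of truth classes at n=20,000."""
        mixture = {"full_length": 0.30, "three_prime_anchored": 0.30,
                   "five_prime_anchored": 0.20, "coat_subgenomic": 0.15,
                   "other_internal": 0.05}
        cfg = SimConfig(seed=seed, n_reads=20_000, error_rate=0.0,
                        class_mixture=mixture)
        truth = simulate_reads(genome, cfg)[3]
        counts = truth["true_class"].value_counts()
        obs = np.array([counts.get(c, 0) for c in sorted(mixture)])
        exp = np.array([mixture[c] * 20_000 for c in sorted(mixture)])
        assert chisquare(obs, exp).pvalue > 0.001


class TestSimulateHybrids:
    def test_pos_pos_deletion_blocks(self, genome):
        seqs, _, truth = simulate_hybrids(
            genome, [("pos_pos_deletion", 5, (30, 30))], seed=1, error_rate=0.0)
        for _, row in truth.iterrows():
            read = seqs[row.read_id]
            j1, j2 = int(row.junction_1), int(row.junction_2)  # 1-based
            assert row.delta == 30 and j2 - j1 == 31
            # the read is genome up to j1 then genome resuming delta later
            k = read.find(genome.sequence[j2 - 1:j2 + 19])
            assert genome.sequence[j1 - 20:j1] in read[:k + 1]

    def test_foldback_construction(self, genome):
        seqs, _, truth = simulate_hybrids(genome, [("foldback", 3, None)],
                                          seed=2, error_rate=0.0)
        assert (truth.true_type == "foldback").all()
        for rid, read in seqs.items():
            # the tail is the reverse complement of a suffix of the head
            assert revcomp(read[-50:]) in read

    def test_zero_delta_rejected(self, genome):
        with pytest.raises(ValueError, match="not a hybrid|delta range"):
            simulate_hybrids(genome, [("pos_pos_deletion", 1, (0, 0))], seed=1)

    def test_neg_neg_junctions_in_genome_frame(self, genome):
        seqs, _, truth = simulate_hybrids(
            genome, [("neg_neg_deletion", 5, (40, 40))], seed=3, error_rate=0.0)
        for _, row in truth.iterrows():
            read = seqs[row.read_id]
            # first segment ends (biological 3') at junction_1 on the genome
            j1 = int(row.junction_1)
            assert revcomp(genome.sequence[j1 - 1:j1 + 19]) in read


class TestSimulateModifications:
    def _reads(self, n, timepoint="0h"):
        return [AlignedRead(read_id=f"r{i}", strand="+", ref_start=100,
                            ref_end=1200, query_length=1100, timepoint=timepoint,
                            sample="test") for i in range(n)]

    def _c_site(self, genome):
        return genome.sequence.index("C", 500)

    def test_full_stoichiometry_forces_high_probability(self, genome):
        recs = simulate_modifications(genome, [(self._c_site(genome), "m5C", 1.0)],
                                      self._reads(100), seed=1)
        assert len(recs) == 100
        assert all(r.probability >= 0.85 for r in recs)

    def test_ivt_suppresses_all_sites(self, genome):
        recs = simulate_modifications(genome, [(self._c_site(genome), "m5C", 0.9)],
                                      self._reads(100), ivt=True, seed=1)
        assert all(r.probability < 0.30 for r in recs)

    def test_stoichiometry_recovered_by_independent_tally(self, genome):
        """Fraction of high-probability calls matches the Bernoulli rate."""
        recs = simulate_modifications(genome, [(self._c_site(genome), "m5C", 0.8)],
                                      self._reads(1000), seed=1)
        frac = np.mean([r.probability >= 0.85 for r in recs])
        # binomial(1000, 0.8): 4 sigma is ~0.05
        assert abs(frac - 0.8) < 0.05

    def test_incompatible_base_rejected(self, genome):
        pos_not_c = genome.sequence.index("A", 500)
        with pytest.raises(ValueError, match="is not C"):
            simulate_modifications(genome, [(pos_not_c, "m5C", 0.5)],
                                   self._reads(10), seed=1)

    def test_minus_strand_reads_emit_nothing(self, genome):
        reads = [AlignedRead(read_id="n", strand="-", ref_start=100, ref_end=1200,
                             query_length=1100, timepoint="0h", sample="test")]
        recs = simulate_modifications(genome, [(self._c_site(genome), "m5C", 1.0)],
                                      reads, seed=1)
        assert recs == []
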
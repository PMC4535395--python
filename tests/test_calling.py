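"""Pileup tallying, conversion QC, threshold calling, differential report."""

import math

import pytest

from rbsmeth.align import Alignment, ReadAligner
from rbsmeth.calling import (
    LOST,
    METHYLATED,
    NO_CALL,
    REDUCED,
    UNCHANGED,
    UNMETHYLATED,
    SitePileup,
    annotate_binomial,
    call_sites,
    differential_sites,
    global_cytosine_abundance,
    percent_methylation,
    qc_conversion,
    tally_pileup,
)
from rbsmeth.errors import AlignmentError, QCError, ValidationError
from rbsmeth.reference import in_silico_convert
from rbsmeth.simulate import SimulationConfig, simulate_bisulfite_reads

from conftest import random_ref_with_c_count


def aln(read_id, ref_id, start, cochampions=None):
    cochampions = frozenset(cochampions or {ref_id})
    return Alignment(read_id, ref_id, start, 0, len(cochampions) > 1, cochampions)


@pytest.mark.parametrize("n_c,n_t,expected", [(4, 6, 0.40), (10, 0, 1.0), (0, 10, 0.0)])
def test_percent_methylation(n_c, n_t, expected):
    assert percent_methylation(n_c, n_t) == pytest.approx(expected)


def test_percent_methylation_undefined_at_zero_coverage():
    assert percent_methylation(0, 0) is None


class TestTally:
    def test_unambiguous_read_counts_fully(self):
        ref = in_silico_convert("r", "AACGAA")  # C at position 3
        pileups = tally_pileup({"q": [aln("q", "r", 1)]}, {"q": "AACGAA"}, [ref])
        site = pileups[0]
        assert (site.reference_id, site.position) == ("r", 3)
        assert site.n_C == 1 and site.n_T == 0
        assert site.methylation == 1.0

    def test_ambiguous_read_counts_half_to_each(self):
        refs = [in_silico_convert("a", "AACGAA"), in_silico_convert("b", "AACGAA")]
        champs = [aln("q", "a", 1, {"a", "b"}), aln("q", "b", 1, {"a", "b"})]
        pileups = tally_pileup({"q": champs}, {"q": "AATGAA"}, refs)
        by_ref = {p.reference_id: p for p in pileups}
        assert by_ref["a"].n_T == pytest.approx(0.5)
        assert by_ref["b"].n_T == pytest.approx(0.5)

    def test_unknown_reference_is_an_error(self):
        ref = in_silico_convert("r", "AACGAA")
        with pytest.raises(AlignmentError):
            tally_pileup({"q": [aln("q", "other", 1)]}, {"q": "AACGAA"}, [ref])

    def test_simulated_site_recovers_truth_within_binomial_error(self, rng):
        """End to end (simulate -> align -> tally) at m=0.66, depth ~100."""
        seq = random_ref_with_c_count(rng, 80, 10)
        pos = seq.index("C") + 1
        config = SimulationConfig(
            seed=21,
            references=(("r", 1.0),),
            methylation_map={("r", pos): 0.66},
            read_length_range=(65, 80),
            n_reads=120,
            seq_error_rate=0.0,
        )
        reads, _ = simulate_bisulfite_reads(config, {"r": seq})
        refset = [in_silico_convert("r", seq)]
        aligner = ReadAligner(refset)
        alignments = {rid: aligner.align(s, rid) for rid, s in reads}
        pileups = tally_pileup(alignments, dict(reads), refset)
        site = next(p for p in pileups if p.position == pos)
        se = math.sqrt(0.66 * 0.34 / site.coverage)
        assert site.coverage >= 50
        assert abs(site.methylation - 0.66) <= 3 * se + (1 - 0.99)

    def test_count_conservation(self, rng):
        """Total tallied mass equals the aligned read bases falling on
        reference cytosine positions, under fractional weights."""
        seq = random_ref_with_c_count(rng, 80, 12)
        refset = [in_silico_convert("r", seq)]
        config = SimulationConfig(
            seed=22, references=(("r", 1.0),), read_length_range=(65, 80), n_reads=80
        )
        reads, _ = simulate_bisulfite_reads(config, {"r": seq})
        aligner = ReadAligner(refset)
        alignments = {rid: aligner.align(s, rid) for rid, s in reads}
        pileups = tally_pileup(alignments, dict(reads), refset)
        tallied = sum(p.n_C + p.n_T + p.n_other for p in pileups)
        c_set = set(refset[0].c_positions)
        expected = sum(
            a.weight * sum(1 for p in c_set if a.start <= p < a.start + len(dict(reads)[rid]))
            for rid, champs in alignments.items()
            for a in champs
        )
        assert tallied == pytest.approx(expected)


class TestConversionQC:
    def test_all_t_control_passes(self):
        piles = [SitePileup("ctl", p, n_C=0, n_T=50) for p in (3, 9, 17)]
        qc = qc_conversion(piles)
        assert qc.global_conversion == 1.0 and qc.passed

    def test_uncovered_control_is_an_error(self):
        with pytest.raises(QCError):
            qc_conversion([SitePileup("ctl", 3)])

    @pytest.mark.parametrize("e,should_pass", [(0.95, False), (0.99, True)])
    def test_simulated_efficiency_gates_correctly(self, e, should_pass, rng):
        control_seq = random_ref_with_c_count(rng, 300, 60)
        config = SimulationConfig(
            seed=23,
            references=(("ctl", 1.0),),
            conversion_efficiency=e,
            read_length_range=(65, 95),
            n_reads=400,
            seq_error_rate=0.0,
        )
        reads, _ = simulate_bisulfite_reads(config, {"ctl": control_seq})
        refset = [in_silico_convert("ctl", control_seq)]
        aligner = ReadAligner(refset)
        alignments = {rid: aligner.align(s, rid) for rid, s in reads}
        pileups = tally_pileup(alignments, dict(reads), refset)
        qc = qc_conversion(pileups)
        assert qc.passed is should_pass
        if not should_pass:
            with pytest.raises(QCError):
                call_sites(pileups, qc=qc)


class TestCallSites:
    def test_threshold_matrix(self):
        piles = [
            SitePileup("r", 5, n_C=4, n_T=0),  # coverage 4 -> no_call
            SitePileup("r", 10, n_C=1.9, n_T=8.1),  # 19% -> unmethylated
            SitePileup("r", 15, n_C=1.0, n_T=4.0),  # cov 5, 20% -> methylated
            SitePileup("r", 20, n_C=66, n_T=34),  # 66% -> methylated
            SitePileup("r", 25, n_C=5, n_T=95),  # 5% -> unmethylated
        ]
        calls = {c.position: c.status for c in call_sites(piles)}
        assert calls == {5: NO_CALL, 10: UNMETHYLATED, 15: METHYLATED, 20: METHYLATED, 25: UNMETHYLATED}

    def test_binomial_annotation_orders_by_evidence(self):
        piles = [SitePileup("r", 1, n_C=66, n_T=34), SitePileup("r", 2, n_C=2, n_T=98)]
        calls = annotate_binomial(call_sites(piles), null_rate=0.01)
        assert calls[0].p_value < calls[1].p_value
        assert calls[0].p_value < 1e-10


class TestGlobalCytosineAbundance:
    def test_fully_converted_library_has_zero(self):
        alignments = {"q": [aln("q", "r", 1)]}
        assert global_cytosine_abundance(alignments, {"q": "ATTGAT"}) == 0.0

    def test_unconverted_reads_reflect_composition(self):
        alignments = {"q": [aln("q", "r", 1)]}
        assert global_cytosine_abundance(alignments, {"q": "ACCGAT"}) == pytest.approx(2 / 6)

    def test_spikein_excluded(self):
        alignments = {"q": [aln("q", "ctl", 1)], "p": [aln("p", "r", 1)]}
        reads = {"q": "CCCCCC", "p": "ATTGAT"}
        frac = global_cytosine_abundance(alignments, reads, exclude_references={"ctl"})
        assert frac == 0.0


class TestDifferential:
    def make_call(self, pos, n_c, n_t, min_cov=5):
        return call_sites([SitePileup("r", pos, n_C=n_c, n_T=n_t)], min_coverage=min_cov)[0]

    def test_lost_reduced_unchanged_and_exclusion(self):
        wt = [
            self.make_call(1, 66, 34),  # 66% -> lost in mutant (2%)
            self.make_call(2, 90, 10),  # 90% -> reduced to 60%
            self.make_call(3, 50, 50),  # 50% -> unchanged
            self.make_call(4, 2, 2),  # no_call -> excluded
        ]
        mut = [
            self.make_call(1, 2, 98),
            self.make_call(2, 60, 40),
            self.make_call(3, 45, 55),
            self.make_call(4, 100, 0),
        ]
        report = differential_sites(wt, mut).set_index("position")
        assert report.loc[1, "change"] == LOST
        assert report.loc[2, "change"] == REDUCED
        assert report.loc[3, "change"] == UNCHANGED
        assert 4 not in report.index

    def test_mismatched_reference_sets_rejected(self):
        with pytest.raises(ValidationError):
            differential_sites([self.make_call(1, 5, 5)], [self.make_call(2, 5, 5)])
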
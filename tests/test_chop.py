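"""Methyl-chop PCR / dCAPS digest prediction."""

import pytest

from rbsmeth.assays import (
    ASP_C38_POSITION,
    ASP_GTC_TEMPLATE,
    RRNA_SITE_POSITION,
    RRNA_TEMPLATE,
    asp_chop_assay,
    asp_chop_primers,
    rrna_dcaps_assay,
)
from rbsmeth.chop import (
    HINFI,
    HPYCH4IV,
    DCAPSPrimer,
    Enzyme,
    bs_convert_template,
    build_amplicon,
    digest,
    render_gel,
)
from rbsmeth.errors import AssayError, ValidationError
from rbsmeth.reference import in_silico_convert

from conftest import random_dna


class TestBsConvertTemplate:
    @pytest.mark.parametrize(
        "seq,protected,expected",
        [
            ("ACGT", {2}, "ACGT"),
            ("ACGT", set(), "ATGT"),
            ("CACGTC", {3}, "TACGTT"),
        ],
    )
    def test_examples(self, seq, protected, expected):
        assert bs_convert_template(seq, protected) == expected

    def test_non_cytosine_position_rejected(self):
        with pytest.raises(ValidationError):
            bs_convert_template("ACGT", {1})

    def test_all_methylated_is_identity_none_equals_conversion(self, rng):
        for _ in range(20):
            seq = random_dna(rng, 60)
            all_c = {i + 1 for i, b in enumerate(seq) if b == "C"}
            assert bs_convert_template(seq, all_c) == seq
            assert bs_convert_template(seq, set()) == in_silico_convert("x", seq).converted_sequence


class TestDigest:
    def test_single_site_cut_position(self):
        # ACGT at positions 3-6 of a 10-mer; HpyCH4IV cuts after the A.
        pred = digest("AAACGTAAAA", HPYCH4IV)
        assert pred.cut_positions == (3,)
        assert pred.fragment_lengths == (3, 7)
        assert pred.digested

    def test_no_site_is_undigested(self):
        pred = digest("A" * 40, HINFI)
        assert not pred.digested
        assert pred.fragment_lengths == (40,)

    def test_iupac_n_in_recognition(self):
        assert digest("AAGAATCAAA", HINFI).digested  # GANTC matches GAATC
        assert digest("AAGATTCAAA", HINFI).digested
        assert not digest("AAGAAACAAA", HINFI).digested

    def test_fragments_always_sum_to_amplicon_length(self, rng):
        for _ in range(300):
            seq = random_dna(rng, int(rng.integers(20, 150)))
            for enzyme in (HPYCH4IV, HINFI):
                pred = digest(seq, enzyme)
                assert sum(pred.fragment_lengths) == len(seq)

    def test_concatenation_yields_union_of_fragments(self, rng):
        """Digesting A+B (no site spanning the junction) merges only the two
        junction-adjacent fragments."""
        from rbsmeth.seqtools import find_iupac

        checked = 0
        while checked < 50:
            a, b = random_dna(rng, 80), random_dna(rng, 80)
            joined = a + b
            spans_junction = any(
                p < 80 < p + len(HPYCH4IV.recognition)
                for p in find_iupac(HPYCH4IV.recognition, joined)
            )
            if spans_junction:
                continue
            fa, fb = digest(a, HPYCH4IV), digest(b, HPYCH4IV)
            fj = digest(joined, HPYCH4IV)
            merged = list(fa.fragment_lengths) + list(fb.fragment_lengths)
            # a's junction-adjacent fragment merges with b's
            a_last = len(a) if not fa.cut_positions else len(a) - fa.cut_positions[-1]
            b_first = len(b) if not fb.cut_positions else fb.cut_positions[0]
            merged.remove(a_last)
            merged.remove(b_first)
            merged.append(a_last + b_first)
            assert sorted(fj.fragment_lengths) == sorted(merged)
            checked += 1

    def test_reverse_strand_site_for_non_palindromic_enzyme(self):
        # EcoP15I-like asymmetric toy enzyme: CAGCAG, cut inside at offset 2.
        toy = Enzyme("toy", "CAGCAG", 2)
        # reverse complement of the site on the top strand
        pred = digest("AAAACTGCTGAAAA", toy)
        assert pred.digested


class TestAmplicon:
    def test_exact_end_primers_return_template(self, rng):
        template = random_dna(rng, 100)
        from rbsmeth.seqtools import reverse_complement

        fwd = DCAPSPrimer("f", template[:20])
        rev = DCAPSPrimer("r", reverse_complement(template[-20:]))
        amplicon, start = build_amplicon(template, fwd, rev)
        assert amplicon == template and start == 1

    def test_internal_mismatch_is_incorporated(self, rng):
        template = random_dna(rng, 100)
        from rbsmeth.seqtools import reverse_complement

        fwd_seq = list(template[:20])
        fwd_seq[10] = {"A": "G", "G": "A", "C": "T", "T": "C"}[fwd_seq[10]]
        fwd = DCAPSPrimer("f", "".join(fwd_seq))
        rev = DCAPSPrimer("r", reverse_complement(template[-20:]))
        amplicon, _ = build_amplicon(template, fwd, rev)
        assert amplicon[10] == fwd_seq[10] != template[10]

    def test_three_prime_mismatch_blocks_annealing(self, rng):
        template = random_dna(rng, 100)
        from rbsmeth.seqtools import reverse_complement

        fwd_seq = list(template[:20])
        fwd_seq[19] = {"A": "G", "G": "A", "C": "T", "T": "C"}[fwd_seq[19]]
        fwd = DCAPSPrimer("f", "".join(fwd_seq))
        rev = DCAPSPrimer("r", reverse_complement(template[-20:]))
        with pytest.raises(AssayError, match="does not anneal"):
            build_amplicon(template, fwd, rev)

    def test_multiple_annealing_sites_rejected(self):
        template = ("ATGAGGATTAGGATAGATTAGG" * 2) + "AAAATTTTGGGGAAAATTTTG"
        fwd = DCAPSPrimer("f", template[:20])
        rev = DCAPSPrimer("r", "CAAAATTTT")
        with pytest.raises(AssayError, match="multiple"):
            build_amplicon(template, fwd, rev)


class TestWorkedAssays:
    def test_asp_trna_c38_chop(self):
        """72 bp amplicon; HpyCH4IV cuts 35 + 37 bp only when C38 is
        methylated (the conversion-destroyed site leaves it uncut)."""
        report = asp_chop_assay()
        assert report.methylated.amplicon_length == 72
        assert report.methylated.fragment_lengths == (35, 37)
        assert report.unmethylated.fragment_lengths == (72,)
        assert not report.unmethylated.digested
        assert report.informative

    def test_rrna_dcaps_c2268_like_assay(self):
        """155 bp dCAPS product; HinfI cuts 29 + 126 bp only when the
        diagnostic cytosine is methylated."""
        report = rrna_dcaps_assay()
        assert report.methylated.amplicon_length == 155
        assert report.methylated.fragment_lengths == (29, 126)
        assert report.unmethylated.fragment_lengths == (155,)
        assert report.informative

    def test_dcaps_mismatch_primer_is_required(self):
        assert not rrna_dcaps_assay(with_mismatch=False).informative

    def test_site_outside_amplicon_rejected(self):
        fwd, rev = asp_chop_primers()
        template = ASP_GTC_TEMPLATE + "C" + "A" * 30
        from rbsmeth.chop import assay_report

        with pytest.raises(AssayError, match="outside"):
            # primers still frame the original 72 bp; the site lies beyond
            assay_report(template, len(ASP_GTC_TEMPLATE) + 1, HPYCH4IV, fwd, rev)

    def test_virtual_gel_renders_both_lanes(self):
        gel = render_gel(asp_chop_assay())
        assert "35bp" in gel.replace(" ", "") and "72bp" in gel.replace(" ", "")
        assert "informative" in gel
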
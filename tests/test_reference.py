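"""Reference construction: isodecoder collapsing and in-silico conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbsmeth.errors import ValidationError
from rbsmeth.reference import (
    RRNAReference,
    TRNAGeneRecord,
    collapse_isodecoders,
    derive_species_rrna,
    in_silico_convert,
    pairwise_identity,
)

from conftest import random_dna

SEQ72 = "GGAGAGATAGTTTAATGGTAGAATAGGAGTTTGGTCACGTGGTTTAAAGGTAGAGTTGGTTTAAATTGAAGG"


def gene(gene_id, genome, seq=SEQ72, aa="Asp", anticodon="GTC"):
    return TRNAGeneRecord(gene_id, genome, aa, anticodon, seq)


class TestInSilicoConvert:
    @pytest.mark.parametrize(
        "seq, converted, positions",
        [
            ("ACGT", "ATGT", (2,)),
            ("AGTA", "AGTA", ()),
            ("CCCC", "TTTT", (1, 2, 3, 4)),
            ("ANCN", "ANTN", (3,)),  # N never counts as a cytosine
        ],
    )
    def test_examples(self, seq, converted, positions):
        ref = in_silico_convert("x", seq)
        assert ref.converted_sequence == converted
        assert ref.c_positions == positions
        assert "C" not in ref.converted_sequence

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValidationError):
            in_silico_convert("x", "ACGU")

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=120))
    def test_round_trip_restores_source(self, seq):
        ref = in_silico_convert("x", seq)
        assert ref.restore() == seq
        assert len(ref.converted_sequence) == len(seq)


class TestCollapse:
    def test_identical_genes_collapse_to_one_consensus(self):
        out = collapse_isodecoders([gene("g1", "nuclear"), gene("g2", "nuclear")])
        assert len(out) == 1
        assert out[0].consensus_id == "Asp-GTC"
        assert out[0].sequence == SEQ72
        assert out[0].member_gene_ids == {"g1", "g2"}
        assert out[0].genomes == {"nuclear"}

    def test_multi_genome_origin_is_unioned(self):
        out = collapse_isodecoders([gene("g1", "nuclear"), gene("g2", "chloroplast")])
        assert len(out) == 1
        assert out[0].genomes == {"nuclear", "chloroplast"}

    def test_minority_isodecoder_gets_suffix(self, rng):
        """Two identical Gly(GCC) genes plus one with 8 substitutions
        (88.9% identity, below 0.95) partition into majority + '-1'
        minority, matching an exhaustive single-linkage over all pairs."""
        base = random_dna(rng, 72)
        diverged = list(base)
        for pos in rng.choice(72, size=8, replace=False):
            diverged[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[diverged[pos]]
        diverged = "".join(diverged)
        genes = [
            gene("a", "nuclear", base, "Gly", "GCC"),
            gene("b", "nuclear", base, "Gly", "GCC"),
            gene("c", "nuclear", diverged, "Gly", "GCC"),
        ]
        # independent oracle: all-pairs identity + transitive closure
        assert pairwise_identity(base, diverged) < 0.95
        out = collapse_isodecoders(genes)
        by_id = {c.consensus_id: c for c in out}
        assert set(by_id) == {"Gly-GCC", "Gly-GCC-1"}
        assert by_id["Gly-GCC"].member_gene_ids == {"a", "b"}
        assert by_id["Gly-GCC-1"].member_gene_ids == {"c"}

    def test_empty_input_gives_empty_output(self):
        assert collapse_isodecoders([]) == []

    def test_high_n_content_rejected(self):
        with pytest.raises(ValidationError):
            gene("g1", "nuclear", "N" * 20 + SEQ72[20:])

    def test_partition_property(self, rng):
        """Every input gene belongs to exactly one consensus."""
        genes = [
            gene(f"g{i}", "nuclear", random_dna(rng, 72), "Ser", "GCT") for i in range(8)
        ]
        out = collapse_isodecoders(genes)
        members = [gid for c in out for gid in c.member_gene_ids]
        assert sorted(members) == sorted(g.gene_id for g in genes)

    def test_collapsing_is_idempotent(self, rng):
        genes = [gene(f"g{i}", "nuclear", random_dna(rng, 72), "Ser", "GCT") for i in range(6)]
        first = collapse_isodecoders(genes)
        again = collapse_isodecoders(
            [
                TRNAGeneRecord(c.consensus_id, "nuclear", "Ser", "GCT", c.sequence)
                for c in first
                if set(c.sequence) <= set("ACGTN")
            ]
        )
        assert len(again) == len(first)
        assert {c.sequence for c in again} == {c.sequence for c in first}

    def test_cluster_count_monotone_in_threshold(self, rng):
        base = random_dna(rng, 72)
        variants = []
        for i in range(6):
            seq = list(base)
            for pos in rng.choice(72, size=i * 2, replace=False):
                seq[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[seq[pos]]
            variants.append("".join(seq))
        genes = [gene(f"g{i}", "nuclear", s, "His", "GTG") for i, s in enumerate(variants)]
        counts = [
            len(collapse_isodecoders(genes, identity_threshold=t))
            for t in (0.99, 0.95, 0.90, 0.80, 0.60)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_tie_becomes_iupac_code(self):
        a = SEQ72
        b = SEQ72[:10] + ("A" if SEQ72[10] != "A" else "G") + SEQ72[11:]
        out = collapse_isodecoders([gene("g1", "nuclear", a), gene("g2", "nuclear", b)])
        assert len(out) == 1
        assert out[0].sequence[10] not in "ACGT"  # ambiguity code at the tied column


class TestDeriveSpeciesRRNA:
    def make_anchor(self, rng, length=300):
        return RRNAReference("nuclear-25S", "nuclear", "LSU", random_dna(rng, length))

    def reads_from(self, rng, seq, n, length=60):
        reads = []
        for i in range(n):
            start = int(rng.integers(0, len(seq) - length + 1))
            reads.append((f"r{i}", seq[start : start + length]))
        return reads

    def test_identical_reads_return_anchor(self, rng):
        anchor = self.make_anchor(rng)
        out = derive_species_rrna(self.reads_from(rng, anchor.sequence, 200), anchor, min_depth=5)
        assert out.sequence == anchor.sequence

    def test_known_snps_recovered(self, rng):
        anchor = self.make_anchor(rng)
        mutated = list(anchor.sequence)
        snp_positions = sorted(int(p) for p in rng.choice(np.arange(30, 270), size=5, replace=False))
        for pos in snp_positions:
            mutated[pos - 1] = {"A": "G", "G": "A", "C": "T", "T": "C"}[mutated[pos - 1]]
        mutated = "".join(mutated)
        reads = self.reads_from(rng, mutated, 600)  # depth ~ 50+ everywhere
        out = derive_species_rrna(reads, anchor, min_depth=20, species="Td")
        for pos in snp_positions:
            assert out.sequence[pos - 1] == mutated[pos - 1]
        # untouched positions keep the anchor base
        assert sum(a != b for a, b in zip(out.sequence, mutated)) == 0

    def test_zero_aligned_reads_is_an_error(self, rng):
        anchor = self.make_anchor(rng)
        with pytest.raises(ValidationError, match="nuclear-25S"):
            derive_species_rrna([("r0", "A" * 60)], anchor)
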
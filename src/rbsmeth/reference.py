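"""Reference construction: tRNA isodecoder collapsing and converted references.

Plant genomes carry hundreds of near-identical tRNA gene copies; mapping
short reads against them individually makes almost every read ambiguous.
Identical and highly similar isodecoder sequences (same amino acid, same
anticodon) are therefore collapsed into consensus references before
alignment. Minority isodecoders whose body sequence diverges past the
identity threshold stay separate and are numbered "-1", "-2", ... after the
majority consensus.

Bisulfite conversion turns every unmethylated C into T, so reads are mapped
against *in silico* converted references in which every cytosine has been
replaced by thymine; the original cytosine coordinates are retained so the
methylation tally knows where to look.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

from Bio import Align

from rbsmeth.align import ReadAligner
from rbsmeth.errors import ValidationError
from rbsmeth.seqtools import IUPAC_FOR_BASES, c_positions, validate_dna

GENOMES = ("nuclear", "chloroplast", "mitochondrial")
MAX_N_FRACTION = 0.10
DEFAULT_IDENTITY = 0.95


@dataclass(frozen=True)
class TRNAGeneRecord:
    """One annotated mature tRNA gene (intron-free, sense strand, DNA)."""

    gene_id: str
    genome: str
    amino_acid: str
    anticodon: str
    sequence: str

    def __post_init__(self):
        if self.genome not in GENOMES:
            raise ValidationError(f"genome must be one of {GENOMES}, got {self.genome!r}")
        if len(self.anticodon) != 3:
            raise ValidationError(f"anticodon must be 3 nt, got {self.anticodon!r}")
        seq = validate_dna(self.sequence, what=f"gene {self.gene_id}")
        object.__setattr__(self, "sequence", seq)
        if seq.count("N") > MAX_N_FRACTION * len(seq):
            raise ValidationError(
                f"gene {self.gene_id} has >{MAX_N_FRACTION:.0%} N content"
            )


@dataclass(frozen=True)
class ConsensusIsodecoder:
    """A collapsed isodecoder consensus and its member genes."""

    consensus_id: str
    sequence: str
    member_gene_ids: frozenset[str]
    genomes: frozenset[str]


@dataclass(frozen=True)
class RRNAReference:
    """One rRNA species sequence (e.g. nuclear 25S LSU)."""

    rrna_id: str
    genome: str
    subunit: str
    sequence: str
    low_depth_positions: tuple[int, ...] = ()

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"rRNA {self.rrna_id} has empty sequence")
        if self.genome not in GENOMES:
            raise ValidationError(f"genome must be one of {GENOMES}, got {self.genome!r}")
        if self.subunit not in ("LSU", "SSU"):
            raise ValidationError(f"subunit must be LSU or SSU, got {self.subunit!r}")
        object.__setattr__(self, "sequence", validate_dna(self.sequence, what=self.rrna_id))


@dataclass(frozen=True)
class ConvertedReference:
    """An in-silico bisulfite-converted reference (every C -> T).

    ``c_positions`` are the 1-based coordinates that were cytosine in the
    source, i.e. the only positions at which methylation can be observed.
    """

    source_id: str
    converted_sequence: str
    c_positions: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.converted_sequence)

    def restore(self) -> str:
        """Undo the conversion (round-trip back to the source sequence)."""
        chars = list(self.converted_sequence)
        for pos in self.c_positions:
            chars[pos - 1] = "C"
        return "".join(chars)


def in_silico_convert(source_id: str, sequence: str) -> ConvertedReference:
    """C->T convert a reference, recording original cytosine positions."""
    seq = validate_dna(sequence, what=f"reference {source_id}")
    return ConvertedReference(
        source_id=source_id,
        converted_sequence=seq.replace("C", "T"),
        c_positions=tuple(c_positions(seq)),
    )


# ---------------------------------------------------------------------------
# isodecoder collapsing

def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global identity: identical aligned pairs / length of the longer sequence."""
    if a == b:
        return 1.0
    aligner = aligner or _identity_aligner()
    alignment = aligner.align(a, b)[0]
    matches = sum(
        a[i] == b[j]
        for (astart, aend), (bstart, bend) in zip(*alignment.aligned)
        for i, j in zip(range(astart, aend), range(bstart, bend))
    )
    return matches / max(len(a), len(b))


def _single_linkage(sequences: Sequence[str], threshold: float) -> list[list[int]]:
    """Cluster indices by single linkage at pairwise identity >= threshold."""
    n = len(sequences)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    aligner = _identity_aligner()
    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if pairwise_identity(sequences[i], sequences[j], aligner) >= threshold:
                parent[find(j)] = find(i)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


def _consensus_sequence(sequences: Sequence[str]) -> str:
    """Per-position majority base; ties become IUPAC ambiguity codes.

    Length-heterogeneous members are pairwise-aligned to a modal-length
    anchor and vote per anchor column; insertions relative to the anchor do
    not vote.
    """
    lengths = Counter(len(s) for s in sequences)
    modal_length = max(lengths, key=lambda length: (lengths[length], length))
    anchor = min(s for s in sequences if len(s) == modal_length)
    columns: list[Counter] = [Counter() for _ in range(modal_length)]
    aligner = _identity_aligner()
    for seq in sequences:
        if len(seq) == modal_length:
            for col, base in enumerate(seq):
                columns[col][base] += 1
        else:
            alignment = aligner.align(anchor, seq)[0]
            for (astart, aend), (bstart, bend) in zip(*alignment.aligned):
                for col, j in zip(range(astart, aend), range(bstart, bend)):
                    columns[col][seq[j]] += 1
    out = []
    for counter in columns:
        counter.pop("N", None)
        if not counter:
            out.append("N")
            continue
        top = max(counter.values())
        winners = frozenset(base for base, count in counter.items() if count == top)
        out.append(IUPAC_FOR_BASES[winners])
    return "".join(out)


def collapse_isodecoders(
    genes: Iterable[TRNAGeneRecord],
    identity_threshold: float = DEFAULT_IDENTITY,
) -> list[ConsensusIsodecoder]:
    """Collapse tRNA genes into isodecoder consensus references.

    Genes are grouped by (amino acid, anticodon) and single-linkage
    clustered at >= ``identity_threshold`` global identity within each
    group. Each cluster yields one consensus; the largest cluster in a
    group is named ``<aa>-<anticodon>`` and minority clusters are suffixed
    ``-1``, ``-2``, ... in decreasing size order. The genome-of-origin set
    of a consensus is the union over its members, so a sequence encoded by
    e.g. both the nuclear and chloroplast genome yields a single consensus
    of ambiguous origin.
    """
    if not 0 < identity_threshold <= 1:
        raise ValidationError("identity_threshold must be in (0, 1]")
    gene_list = list(genes)
    if not gene_list:
        return []
    groups: dict[tuple[str, str], list[TRNAGeneRecord]] = {}
    for gene in gene_list:
        groups.setdefault((gene.amino_acid, gene.anticodon), []).append(gene)

    consensuses: list[ConsensusIsodecoder] = []
    for (aa, anticodon), members in sorted(groups.items()):
        members = sorted(members, key=lambda g: g.gene_id)
        clusters = _single_linkage([g.sequence for g in members], identity_threshold)
        # Majority cluster first; ties broken by smallest member gene_id.
        clusters.sort(key=lambda idxs: (-len(idxs), min(members[i].gene_id for i in idxs)))
        for rank, idxs in enumerate(clusters):
            cluster_genes = [members[i] for i in idxs]
            suffix = "" if rank == 0 else f"-{rank}"
            consensuses.append(
                ConsensusIsodecoder(
                    consensus_id=f"{aa}-{anticodon}{suffix}",
                    sequence=_consensus_sequence([g.sequence for g in cluster_genes]),
                    member_gene_ids=frozenset(g.gene_id for g in cluster_genes),
                    genomes=frozenset(g.genome for g in cluster_genes),
                )
            )
    return consensuses


# ---------------------------------------------------------------------------
# species rRNA consensus from RNA-seq

def derive_species_rrna(
    reads: Iterable[tuple[str, str]],
    anchor: RRNAReference,
    min_depth: int = 10,
    *,
    max_mismatch: int = 6,
    species: str | None = None,
) -> RRNAReference:
    """Derive a species-specific rRNA consensus from ordinary RNA-seq reads.

    Reads (``(read_id, sequence)`` pairs, non-bisulfite) are aligned
    ungapped to the anchor rRNA (normally the Arabidopsis sequence for the
    same subunit); at every position covered by >= ``min_depth`` reads the
    majority base replaces the anchor base, recovering species-specific
    SNPs. Positions below ``min_depth`` keep the anchor base and are listed
    in ``low_depth_positions``.
    """
    aligner = ReadAligner([(anchor.rrna_id, anchor.sequence)], max_mismatch, convert_read=False)
    counts: list[Counter] = [Counter() for _ in range(len(anchor.sequence))]
    n_aligned = 0
    for read_id, seq in reads:
        champs = aligner.align(seq.upper(), read_id)
        if not champs:
            continue
        n_aligned += 1
        start0 = champs[0].start - 1
        for offset, base in enumerate(seq.upper()):
            counts[start0 + offset][base] += 1
    if n_aligned == 0:
        raise ValidationError(f"no reads aligned to anchor {anchor.rrna_id}")
    bases = []
    low_depth = []
    for pos0, counter in enumerate(counts):
        depth = sum(counter.values())
        if depth >= min_depth:
            top = max(counter.values())
            winners = sorted(b for b, c in counter.items() if c == top)
            # Deterministic tie-break: keep anchor base when it ties.
            if anchor.sequence[pos0] in winners:
                bases.append(anchor.sequence[pos0])
            else:
                bases.append(winners[0])
        else:
            bases.append(anchor.sequence[pos0])
            low_depth.append(pos0 + 1)
    rrna_id = f"{species}-{anchor.rrna_id}" if species else f"consensus-{anchor.rrna_id}"
    return RRNAReference(
        rrna_id=rrna_id,
        genome=anchor.genome,
        subunit=anchor.subunit,
        sequence="".join(bases),
        low_depth_positions=tuple(low_depth),
    )
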
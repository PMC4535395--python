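"""Structural coordinate systems for cross-species site comparison.

tRNAs differ in length (D-loop and variable-loop insertions), so sites are
reported on the classical ~72-position cloverleaf numbering: acceptor stem
1-7/66-72, anticodon 34-36, variable region after position 43, T-arm
49-65, discriminator/acceptor end at 72. The mapping anchors the anticodon
triplet at 34-36 and the 3' acceptor end at 72; insertions relative to the
canonical frame (long variable loops) are left unmapped, deletions skip
labels. Sub-numbered insertion positions (e.g. 47a) are deliberately not
assigned.

rRNA sites are numbered on the coordinates of the Arabidopsis reference for
the same subunit: each species sequence is globally aligned to the anchor
and positions lift through match/mismatch columns only.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from rbsmeth.errors import StructureError, ValidationError
from rbsmeth.seqtools import validate_dna

SCAFFOLD_LENGTH = 72
ANTICODON_START = 34  # structural positions 34-36
_N5_CANONICAL = 33  # bases 5' of the anticodon in the canonical frame
_N3_CANONICAL = 36  # bases 3' of the anticodon (labels 37-72)
_POST_ANTICODON = 7  # labels 37-43 anchored to the anticodon
_ACCEPTOR_BLOCK = 24  # labels 49-72 anchored to the 3' end
_VARIABLE_SLOTS = 5  # labels 44-48


@dataclass(frozen=True)
class StructuralMap:
    """Sequence-index (1-based) to structural-position mapping for one tRNA."""

    reference_id: str
    mapping: tuple[tuple[int, int], ...]
    unmapped: frozenset[int]

    def label_for(self, index: int) -> int | None:
        return dict(self.mapping).get(index)

    def index_for(self, label: int) -> int | None:
        return {lab: idx for idx, lab in self.mapping}.get(label)


@dataclass(frozen=True)
class CoordinateLift:
    """Species rRNA position -> anchor (Arabidopsis) position map."""

    species_rrna_id: str
    anchor_rrna_id: str
    position_map: dict[int, int]
    unmappable: frozenset[int]
    identity: float
    low_identity: bool

    def lift(self, position: int) -> int | None:
        return self.position_map.get(position)


def _anchor_score(n5: int, n3: int) -> int:
    """Deviation of the flanking segment lengths from the canonical frame."""
    return abs(n5 - _N5_CANONICAL) + abs(n3 - _N3_CANONICAL)


def assign_trna_structure(
    sequence: str,
    anticodon: str,
    reference_id: str = "tRNA",
) -> StructuralMap:
    """Map a tRNA sequence onto the canonical 72-position cloverleaf frame.

    The anticodon is anchored at structural 34-36; when it occurs more than
    once the placement whose flanking segments best fit the canonical frame
    wins, and an exact tie raises listing the candidates. The 3' acceptor
    end is counted back from 72, so the discriminator base is always 72;
    surplus variable-loop bases are unmapped and deficits skip labels.
    """
    seq = validate_dna(sequence, what=reference_id)
    anticodon = validate_dna(anticodon, what="anticodon")
    if not 60 <= len(seq) <= 100:
        raise ValidationError(f"{reference_id}: tRNA length {len(seq)} outside 60-100 nt")

    occurrences = []
    pos = seq.find(anticodon)
    while pos != -1:
        occurrences.append(pos + 1)
        pos = seq.find(anticodon, pos + 1)
    if not occurrences:
        raise StructureError(f"{reference_id}: anticodon {anticodon} not found in sequence")
    scored = sorted(
        (_anchor_score(p - 1, len(seq) - p - 2), p) for p in occurrences
    )
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        ties = [p for s, p in scored if s == scored[0][0]]
        raise StructureError(
            f"{reference_id}: anticodon placement ambiguous at offsets {ties}"
        )
    p = scored[0][1]
    n5 = p - 1
    n3 = len(seq) - p - 2

    mapping: list[tuple[int, int]] = []
    unmapped: set[int] = set()

    # 5' side, right-anchored at label 33 (adjacent to the anticodon).
    if n5 <= _N5_CANONICAL:
        for i in range(1, n5 + 1):
            mapping.append((i, _N5_CANONICAL - n5 + i))
    else:
        for i in range(1, n5 - _N5_CANONICAL + 1):
            unmapped.add(i)
        for i in range(n5 - _N5_CANONICAL + 1, n5 + 1):
            mapping.append((i, i - (n5 - _N5_CANONICAL)))

    # Anticodon anchor.
    for k in range(3):
        mapping.append((p + k, ANTICODON_START + k))

    # 3' side: post-anticodon block, variable region, acceptor block.
    first3 = p + 3  # sequence index of the first base after the anticodon
    front = min(n3, _POST_ANTICODON)
    for k in range(front):
        mapping.append((first3 + k, 37 + k))
    if n3 > _POST_ANTICODON:
        back = min(n3 - _POST_ANTICODON, _ACCEPTOR_BLOCK)
        back_start = len(seq) - back + 1
        middle = list(range(first3 + front, back_start))
        for rank, idx in enumerate(middle):
            if rank < _VARIABLE_SLOTS:
                mapping.append((idx, 44 + rank))
            else:
                unmapped.add(idx)
        for k in range(back):
            mapping.append((back_start + k, SCAFFOLD_LENGTH - back + 1 + k))

    mapping.sort()
    return StructuralMap(
        reference_id=reference_id,
        mapping=tuple(mapping),
        unmapped=frozenset(unmapped),
    )


def _lift_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def lift_rrna_position(
    species_seq: str,
    anchor_seq: str,
    species_rrna_id: str = "species",
    anchor_rrna_id: str = "anchor",
    low_identity_threshold: float = 0.50,
) -> CoordinateLift:
    """Lift species rRNA coordinates onto the anchor's numbering.

    Global pairwise alignment (match +1, mismatch -1, gap open -5, extend
    -1); species positions aligned in match/mismatch columns map to the
    anchor position of that column, gap columns are unmappable. A lift with
    identity below ``low_identity_threshold`` is flagged (likely wrong
    subunit or unalignable region) rather than rejected.
    """
    species = validate_dna(species_seq, what=species_rrna_id)
    anchor = validate_dna(anchor_seq, what=anchor_rrna_id)
    if not species or not anchor:
        raise ValidationError("sequences must be non-empty")
    alignment = _lift_aligner().align(species, anchor)[0]
    position_map: dict[int, int] = {}
    matches = 0
    for (sstart, send), (astart, aend) in zip(*alignment.aligned):
        for i, j in zip(range(sstart, send), range(astart, aend)):
            position_map[i + 1] = j + 1
            if species[i] == anchor[j]:
                matches += 1
    identity = matches / max(len(species), len(anchor))
    unmappable = frozenset(set(range(1, len(species) + 1)) - set(position_map))
    return CoordinateLift(
        species_rrna_id=species_rrna_id,
        anchor_rrna_id=anchor_rrna_id,
        position_map=position_map,
        unmappable=unmappable,
        identity=identity,
        low_identity=identity < low_identity_threshold,
    )
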
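"""Ungapped bisulfite read alignment in three-letter (C=T collapsed) space.

Reads from a bisulfite-converted library carry T wherever an unmethylated C
was deaminated, and C only where a cytosine resisted conversion (candidate
m5C). Matching the C->T converted read against C->T converted references
("three-letter alignment") therefore scores an unconverted methylated C as a
match rather than a mismatch, while preserving the original read bases for
the downstream methylation tally.

The aligner is a seed-and-extend index over k-mers of the converted
references. For a mismatch allowance ``m`` the converted read is split into
``m + 1`` disjoint seeds, so any ungapped placement with at most ``m``
mismatches contains at least one exact seed (pigeonhole); the index is
therefore lossless and the result set equals an exhaustive scan over every
offset of every reference, which the test suite verifies against an
independent brute-force scorer.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

from rbsmeth.errors import AlignmentError, ValidationError

MIN_READ_LENGTH = 20
DEFAULT_MAX_MISMATCH = 2
MAX_SEED_LENGTH = 12


@dataclass(frozen=True)
class Alignment:
    """A best-scoring ungapped placement of one read on one reference.

    ``start`` is 1-based on the reference. ``mismatches`` counts differences
    in three-letter space. When several references tie at the minimal
    mismatch count the read is ``ambiguous`` and every tied reference
    appears both as its own Alignment and in ``cochampions``.
    """

    read_id: str
    reference_id: str
    start: int
    mismatches: int
    ambiguous: bool
    cochampions: frozenset[str]

    @property
    def weight(self) -> float:
        """Fractional pileup weight: 1 / number of co-champion references."""
        return 1.0 / len(self.cochampions)


def _normalise_refs(refset) -> list[tuple[str, str]]:
    """Accept ConvertedReference-like objects or (id, sequence) pairs."""
    refs: list[tuple[str, str]] = []
    for ref in refset:
        if isinstance(ref, tuple):
            refs.append((ref[0], ref[1].upper()))
        else:
            refs.append((ref.source_id, ref.converted_sequence.upper()))
    if not refs:
        raise ValidationError("reference set is empty")
    # Deterministic tie resolution: lexicographic reference order.
    refs.sort(key=lambda item: item[0])
    return refs


class ReadAligner:
    """Reusable aligner over a fixed reference panel.

    Parameters
    ----------
    refset:
        Converted references (or ``(id, sequence)`` pairs already in
        matching space, e.g. unconverted references for ordinary RNA-seq).
    max_mismatch:
        Maximum tolerated mismatches in matching space (default 2).
    convert_read:
        When True (bisulfite mode) reads are C->T collapsed before matching.
    """

    def __init__(self, refset, max_mismatch: int = DEFAULT_MAX_MISMATCH, *, convert_read: bool = True):
        if max_mismatch < 0:
            raise ValidationError("max_mismatch must be non-negative")
        self.refs = _normalise_refs(refset)
        self.max_mismatch = max_mismatch
        self.convert_read = convert_read
        self._indices: dict[int, dict[str, list[tuple[int, int]]]] = {}

    def _index(self, k: int) -> dict[str, list[tuple[int, int]]]:
        index = self._indices.get(k)
        if index is None:
            index = {}
            for ref_idx, (_, seq) in enumerate(self.refs):
                for pos in range(len(seq) - k + 1):
                    index.setdefault(seq[pos : pos + k], []).append((ref_idx, pos))
            self._indices[k] = index
        return index

    def align(self, read: str, read_id: str = "read") -> list[Alignment]:
        read = read.upper()
        if len(read) < MIN_READ_LENGTH:
            raise ValidationError(
                f"read {read_id!r} is {len(read)} nt; minimum is {MIN_READ_LENGTH}"
            )
        query = read.replace("C", "T") if self.convert_read else read
        n_seeds = self.max_mismatch + 1
        k = min(MAX_SEED_LENGTH, len(query) // n_seeds)
        if k < 1:
            raise ValidationError("read too short for the requested mismatch allowance")
        index = self._index(k)
        chunk = len(query) // n_seeds

        candidates: set[tuple[int, int]] = set()
        for seed_no in range(n_seeds):
            offset = seed_no * chunk
            for ref_idx, pos in index.get(query[offset : offset + k], ()):
                start = pos - offset
                if start >= 0 and start + len(query) <= len(self.refs[ref_idx][1]):
                    candidates.add((ref_idx, start))

        # Best (mismatches, leftmost start) per reference.
        best: dict[int, tuple[int, int]] = {}
        for ref_idx, start in sorted(candidates):
            seq = self.refs[ref_idx][1]
            limit = self.max_mismatch
            mm = 0
            for qb, rb in zip(query, seq[start : start + len(query)]):
                if qb != rb:
                    mm += 1
                    if mm > limit:
                        break
            if mm > limit:
                continue
            prev = best.get(ref_idx)
            if prev is None or (mm, start) < prev:
                best[ref_idx] = (mm, start)

        if not best:
            return []
        min_mm = min(mm for mm, _ in best.values())
        champions = sorted(
            (self.refs[ref_idx][0], start)
            for ref_idx, (mm, start) in best.items()
            if mm == min_mm
        )
        cochampions = frozenset(ref_id for ref_id, _ in champions)
        ambiguous = len(cochampions) >= 2
        return [
            Alignment(
                read_id=read_id,
                reference_id=ref_id,
                start=start + 1,
                mismatches=min_mm,
                ambiguous=ambiguous,
                cochampions=cochampions,
            )
            for ref_id, start in champions
        ]


def align_read(
    read: str,
    refset,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    *,
    convert_read: bool = True,
    read_id: str = "read",
) -> list[Alignment]:
    """Align one read; see :class:`ReadAligner` for batch use."""
    return ReadAligner(refset, max_mismatch, convert_read=convert_read).align(read, read_id)


def align_reads(
    reads: Iterable[tuple[str, str]],
    refset,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    *,
    convert_read: bool = True,
) -> dict[str, list[Alignment]]:
    """Align ``(read_id, sequence)`` pairs; returns per-read champion lists.

    Unaligned reads map to an empty list.
    """
    aligner = ReadAligner(refset, max_mismatch, convert_read=convert_read)
    return {read_id: aligner.align(seq, read_id) for read_id, seq in reads}


def classify_alignment_rate(
    alignments: Mapping[str, Sequence[Alignment]] | Iterable[Alignment],
    total_reads: int,
    categories: Mapping[str, str],
) -> dict[str, float]:
    """Fraction of reads mapped per reference category, plus ``unaligned``.

    ``categories`` maps reference_id -> category label (e.g. "tRNA", "rRNA",
    "spikein"). A read ambiguous across categories contributes fractionally.
    The returned fractions, including ``unaligned``, sum to 1.
    """
    if total_reads <= 0:
        raise ValidationError("total_reads must be positive")
    if isinstance(alignments, Mapping):
        per_read = list(alignments.values())
    else:
        grouped: dict[str, list[Alignment]] = {}
        for aln in alignments:
            grouped.setdefault(aln.read_id, []).append(aln)
        per_read = list(grouped.values())

    fractions: dict[str, float] = {}
    aligned = 0.0
    for champs in per_read:
        if not champs:
            continue
        for aln in champs:
            try:
                category = categories[aln.reference_id]
            except KeyError:
                raise AlignmentError(f"no category for reference {aln.reference_id!r}")
            fractions[category] = fractions.get(category, 0.0) + aln.weight / total_reads
            aligned += aln.weight / total_reads
    fractions["unaligned"] = 1.0 - aligned
    return fractions
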
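"""Small sequence helpers shared across modules.

Coordinates are 1-based and inclusive on the sense (transcript) strand
throughout the package; references are stored as DNA (T, not U).
"""

from __future__ import annotations

from rbsmeth.errors import ValidationError

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

# IUPAC code for each non-empty set of bases; used for consensus ties and
# for matching enzyme recognition sites.
IUPAC_FOR_BASES = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

BASES_FOR_IUPAC = {code: bases for bases, code in IUPAC_FOR_BASES.items()}
BASES_FOR_IUPAC["N"] = frozenset("ACGT")


def validate_dna(sequence: str, *, what: str = "sequence") -> str:
    """Return ``sequence`` upper-cased, or raise if it leaves {A,C,G,T,N}."""
    seq = sequence.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValidationError(f"{what} contains non-DNA characters: {sorted(bad)}")
    return seq


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def c_positions(sequence: str) -> list[int]:
    """1-based positions of cytosines. N never counts as a cytosine."""
    return [i + 1 for i, base in enumerate(sequence) if base == "C"]


def iupac_matches(pattern_char: str, base: str) -> bool:
    """True when ``base`` is compatible with IUPAC ``pattern_char``."""
    return base in BASES_FOR_IUPAC.get(pattern_char, frozenset())


def find_iupac(pattern: str, sequence: str) -> list[int]:
    """All 0-based start offsets where the IUPAC ``pattern`` matches ``sequence``.

    Overlapping matches are all reported.
    """
    hits = []
    plen = len(pattern)
    for start in range(len(sequence) - plen + 1):
        window = sequence[start : start + plen]
        if all(iupac_matches(p, b) for p, b in zip(pattern, window)):
            hits.append(start)
    return hits
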
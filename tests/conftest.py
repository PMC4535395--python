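"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from rbsmeth.reference import in_silico_convert


def brute_force_align(read: str, refs: list[tuple[str, str]], max_mismatch: int, convert: bool = True):
    """Independent exhaustive ungapped scorer.

    Scores every offset of every reference (no index, no early exit beyond
    the mismatch cap) and returns ``(min_mismatches, {(ref_id, leftmost
    best start 1-based)})`` or ``None`` when nothing scores within the cap.
    A position matches iff the characters are equal.
    """
    query = read.upper().replace("C", "T") if convert else read.upper()
    best_per_ref: dict[str, tuple[int, int]] = {}
    for ref_id, seq in refs:
        for start in range(len(seq) - len(query) + 1):
            mm = sum(q != r for q, r in zip(query, seq[start : start + len(query)]))
            prev = best_per_ref.get(ref_id)
            if prev is None or (mm, start) < prev:
                best_per_ref[ref_id] = (mm, start)
    within = {rid: v for rid, v in best_per_ref.items() if v[0] <= max_mismatch}
    if not within:
        return None
    min_mm = min(mm for mm, _ in within.values())
    champs = {(rid, start + 1) for rid, (mm, start) in within.items() if mm == min_mm}
    return min_mm, champs


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def random_ref_with_c_count(rng: np.random.Generator, length: int, n_c: int) -> str:
    """Random sequence with exactly ``n_c`` cytosines."""
    bases = rng.choice(list("AGT"), size=length)
    c_idx = rng.choice(length, size=n_c, replace=False)
    bases[c_idx] = "C"
    return "".join(bases)


@pytest.fixture
def rng():
    return np.random.default_rng(20160901)


@pytest.fixture
def small_refset(rng):
    """Ten random 80-nt references, converted, as an alignment target."""
    refs = [(f"ref{i:02d}", random_dna(rng, 80)) for i in range(10)]
    return refs, [in_silico_convert(rid, seq) for rid, seq in refs]
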
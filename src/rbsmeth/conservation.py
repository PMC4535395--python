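"""Cross-species conservation of methylated sites at homologous positions.

Sites detected in at least one species are compared across species at
shared coordinates (structural tRNA positions, or anchor-species rRNA
numbering) and classified:

* class1 — methylated in every classifiable species;
* class2 — methylated in all but one species, which carries a SNP
  (no cytosine) at the position;
* class3 — methylated in at least one species while the cytosine is
  present but unmethylated in at least one other;
* unclassified — too few classifiable species (fewer than 3), or a
  pattern outside the three classes.

Species whose coverage at the position is below the calling threshold
(no_call) are excluded from the class decision rather than counted as
unmethylated, so low depth cannot demote a class. An ambiguous reference
base (IUPAC code) likewise excludes that species.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

from rbsmeth.calling import METHYLATED, NO_CALL, SiteCall
from rbsmeth.errors import ValidationError

BASE_C = "C"
BASE_SNP = "SNP"
BASE_ABSENT = "absent"
BASE_AMBIGUOUS = "ambiguous"

CLASS1 = "class1"
CLASS2 = "class2"
CLASS3 = "class3"
UNCLASSIFIED = "unclassified"

LOW_BIN = "low"
INTERMEDIATE_BIN = "intermediate"
HIGH_BIN = "high"


def color_bin(methylation: float) -> str:
    """Heat scale used for plotting: 0-40% low (green end), 80-100% high
    (red end), in between intermediate."""
    if not 0.0 <= methylation <= 1.0:
        raise ValidationError(f"methylation {methylation} outside [0, 1]")
    if methylation <= 0.40:
        return LOW_BIN
    if methylation >= 0.80:
        return HIGH_BIN
    return INTERMEDIATE_BIN


@dataclass(frozen=True)
class ConservationCell:
    """One species' state at one shared position."""

    species: str
    rna_id: str
    structural_position: int
    base_state: str
    methylation: float | None

    @property
    def color(self) -> str | None:
        if self.methylation is None or self.base_state != BASE_C:
            return None
        return color_bin(self.methylation)


@dataclass(frozen=True)
class SiteConservationCall:
    """Per-position cross-species pattern and its conservation class."""

    structural_position: int
    cells: tuple[ConservationCell, ...]
    conservation_class: str


def _classify(cells: Sequence[ConservationCell], min_methylation: float, min_classifiable: int) -> str:
    informative = [c for c in cells if c.base_state == BASE_C and c.methylation is not None]
    snps = [c for c in cells if c.base_state == BASE_SNP]
    methylated = [c for c in informative if c.methylation >= min_methylation]
    unmethylated = [c for c in informative if c.methylation < min_methylation]
    if len(informative) + len(snps) < min_classifiable or not methylated:
        return UNCLASSIFIED
    if unmethylated:
        return CLASS3
    if not snps:
        return CLASS1
    if len(snps) == 1:
        return CLASS2
    return UNCLASSIFIED


def build_conservation_table(
    species_calls: Mapping[str, Sequence[SiteCall]],
    position_maps: Mapping[str, Mapping[int, int]],
    species_sequences: Mapping[str, str],
    rna_id: str = "tRNA",
    min_methylation: float = 0.20,
    min_classifiable: int = 3,
) -> list[SiteConservationCall]:
    """Classify conservation of methylation across a species panel.

    ``species_calls`` maps species -> site calls for one homologous RNA;
    ``position_maps`` maps species -> (sequence position -> shared
    coordinate), e.g. a structural map or an anchor lift;
    ``species_sequences`` supplies each species' reference sequence so the
    base state at the shared position can be read off. One row is emitted
    per shared position methylated in at least one species. Species input
    order never affects the classes.
    """
    if len(species_calls) < 2:
        raise ValidationError("conservation requires at least two species")
    for species in species_calls:
        if species not in position_maps:
            raise ValidationError(f"species {species!r} has no structural map")
        if species not in species_sequences:
            raise ValidationError(f"species {species!r} has no reference sequence")

    inverse: dict[str, dict[int, int]] = {
        species: {label: pos for pos, label in mapping.items()}
        for species, mapping in position_maps.items()
    }
    calls_by_pos: dict[str, dict[int, SiteCall]] = {
        species: {c.position: c for c in calls} for species, calls in species_calls.items()
    }

    # Shared positions methylated in >= 1 species.
    interesting: set[int] = set()
    for species, calls in species_calls.items():
        mapping = position_maps[species]
        for call in calls:
            if call.status == METHYLATED and call.position in mapping:
                interesting.add(mapping[call.position])

    table = []
    for label in sorted(interesting):
        cells = []
        for species in sorted(species_calls):
            seq = species_sequences[species]
            pos = inverse[species].get(label)
            if pos is None or not 1 <= pos <= len(seq):
                cells.append(ConservationCell(species, rna_id, label, BASE_ABSENT, None))
                continue
            base = seq[pos - 1]
            if base == "C":
                call = calls_by_pos[species].get(pos)
                meth = None if call is None or call.status == NO_CALL else call.methylation
                cells.append(ConservationCell(species, rna_id, label, BASE_C, meth))
            elif base in "AGT":
                cells.append(ConservationCell(species, rna_id, label, BASE_SNP, None))
            else:
                cells.append(ConservationCell(species, rna_id, label, BASE_AMBIGUOUS, None))
        table.append(
            SiteConservationCall(
                structural_position=label,
                cells=tuple(cells),
                conservation_class=_classify(cells, min_methylation, min_classifiable),
            )
        )
    return table


def conservation_long_table(calls: Sequence[SiteConservationCall]) -> pd.DataFrame:
    """Long-format table (one row per species x position) for circular plots."""
    rows = []
    for site in calls:
        for cell in site.cells:
            rows.append(
                {
                    "species": cell.species,
                    "rna_id": cell.rna_id,
                    "structural_position": cell.structural_position,
                    "base_state": cell.base_state,
                    "methylation": cell.methylation,
                    "color_bin": cell.color,
                    "class": site.conservation_class,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "rna_id",
            "structural_position",
            "base_state",
            "methylation",
            "color_bin",
            "class",
        ],
    )


def class_counts(calls: Sequence[SiteConservationCall]) -> dict[str, int]:
    counts = {CLASS1: 0, CLASS2: 0, CLASS3: 0, UNCLASSIFIED: 0}
    for site in calls:
        counts[site.conservation_class] += 1
    return counts
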
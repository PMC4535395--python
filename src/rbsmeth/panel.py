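"""Bundled synthetic study panel: references, methylation maps, genotypes.

Everything here is generated programmatically (no data files). The panel
emulates a small tRNA methylation study: a handful of isodecoder consensus
references carrying cytosines at the structural positions where plant
nuclear tRNAs are methylated (38, 48, 49, 50, 72), a wild-type methylation
map, a C38-methyltransferase-null mutant map (C38 sites lost), and a
methylation-free spike-in control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rbsmeth.assays import ASP_GTC_TEMPLATE
from rbsmeth.simulate import SpikeInControl, make_spikein_with_c_count
from rbsmeth.structure import assign_trna_structure

_BASES = np.array(list("ACGT"))


def synthetic_trna(anticodon: str, seed: int, length: int = 72, c_structural: tuple[int, ...] = ()) -> str:
    """A random canonical-architecture tRNA: anticodon at 34-36 (unique
    occurrence), cytosines forced at the requested structural positions."""
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        bases = list(rng.choice(_BASES, size=length))
        bases[33:36] = list(anticodon)
        for label in c_structural:
            bases[label - 1] = "C"
        seq = "".join(bases)
        # overlapping occurrences count (str.count misses e.g. TAT in TATAT)
        occurrences, p = 0, seq.find(anticodon)
        while p != -1:
            occurrences += 1
            p = seq.find(anticodon, p + 1)
        if occurrences == 1:
            return seq
    raise RuntimeError("could not place a unique anticodon")


@dataclass(frozen=True)
class StudyPanel:
    """References, per-genotype methylation maps, and the spike-in control."""

    references: tuple[tuple[str, str], ...]
    anticodons: dict[str, str]
    methylation: dict[str, dict[tuple[str, int], float]]
    control: SpikeInControl

    @property
    def reference_dict(self) -> dict[str, str]:
        return dict(self.references)


def bundled_panel(seed: int = 0) -> StudyPanel:
    """The default two-genotype, one-species synthetic panel.

    Wild type carries methylation at C38 (anticodon-loop), C48/C49/C50
    (variable-region) and C72 (acceptor-end) sites at fractions in the
    23-100% range observed for plant nuclear tRNAs; the mutant genotype
    loses the C38 sites entirely, mimicking loss of the C38-specific
    methyltransferase.
    """
    refs = (
        ("Asp-GTC", ASP_GTC_TEMPLATE),
        ("Gly-GCC", synthetic_trna("GCC", seed * 13 + 1, c_structural=(38, 48, 49))),
        ("Glu-CTC", synthetic_trna("CTC", seed * 13 + 2, c_structural=(48, 50))),
        ("Leu-CAA", synthetic_trna("CAA", seed * 13 + 3, c_structural=(48, 72))),
    )
    anticodons = {rid: rid.split("-")[1] for rid, _ in refs}

    # Map structural labels back to sequence positions per reference.
    def site(rid: str, label: int) -> tuple[str, int]:
        seq = dict(refs)[rid]
        smap = assign_trna_structure(seq, anticodons[rid], rid)
        pos = smap.index_for(label)
        assert pos is not None and seq[pos - 1] == "C", (rid, label)
        return (rid, pos)

    wild_type = {
        site("Asp-GTC", 38): 0.80,
        site("Gly-GCC", 38): 0.66,
        site("Gly-GCC", 48): 0.55,
        site("Gly-GCC", 49): 0.90,
        site("Glu-CTC", 48): 0.45,
        site("Glu-CTC", 50): 0.70,
        site("Leu-CAA", 48): 0.85,
        site("Leu-CAA", 72): 0.30,
    }
    mutant = {key: (0.02 if key in (site("Asp-GTC", 38), site("Gly-GCC", 38)) else frac)
              for key, frac in wild_type.items()}

    control = make_spikein_with_c_count(length=1068, n_cytosines=178, seed=seed + 1000)
    return StudyPanel(
        references=refs,
        anticodons=anticodons,
        methylation={"wild_type": wild_type, "mutant": mutant},
        control=control,
    )
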
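"""Bundled synthetic worked-example assays.

The two classic methyl-chop designs — a tRNA-Asp(GTC) C38 HpyCH4IV chop and
a 25S LSU rRNA C2268 HinfI dCAPS — are reproduced here on synthetic
templates constructed to have the same diagnostic geometry as the published
assays: a 72 bp tRNA amplicon whose single ACGT site spans C38 (cut into
35 + 37 bp only when C38 is methylated), and a 155 bp rRNA amplicon where a
forward dCAPS primer carrying a G mismatch at position four from the 3' end
completes a GANTC site only when the diagnostic cytosine is methylated
(cut into 29 + 126 bp). The sequences are synthetic stand-ins, not the
published reference sequences; only the assay arithmetic is anchored.
"""

from __future__ import annotations

import numpy as np

from rbsmeth.chop import HINFI, HPYCH4IV, AssayReport, DCAPSPrimer, assay_report, bs_convert_template
from rbsmeth.seqtools import reverse_complement

# Synthetic 72-nt tRNA-Asp(GTC)-like template: anticodon GTC at 34-36 (its
# single occurrence), ACGT spanning C38 at 37-40, no other cytosines so the
# converted product carries at most the diagnostic C.
ASP_GTC_TEMPLATE = (
    "GGAGAGATAGTTTAATGGTAGAATAGGAGTTTG"  # 1-33, D-side (C-free)
    "GTC"  # 34-36 anticodon
    "ACGT"  # 37-40, HpyCH4IV site when C38 is protected
    "GGTTTAAAGGTAGAGTTGGTTTAAATTGAAGG"  # 41-72, T-side/acceptor (C-free)
)
ASP_C38_POSITION = 38

# Synthetic 155-nt window standing in for 25S LSU helix 70. The diagnostic
# cytosine sits at window position 33 (published numbering would be 2268 =
# window position + RRNA_WINDOW_OFFSET).
RRNA_WINDOW_OFFSET = 2235
RRNA_SITE_POSITION = 33


def _rrna_window() -> str:
    rng = np.random.default_rng(20160229)
    bases = list("".join(rng.choice(list("ACGT"), size=155)))
    # Diagnostic context: primer-introduced G at 29 + template A30/G31/T32 +
    # protected C33 form GANTC; natively position 29 is T, so the site never
    # forms without the dCAPS primer.
    bases[28] = "T"
    bases[29] = "A"
    bases[30] = "G"
    bases[31] = "T"
    bases[32] = "C"
    return "".join(bases)


RRNA_TEMPLATE = _rrna_window()


def asp_chop_primers() -> tuple[DCAPSPrimer, DCAPSPrimer]:
    """Exact-match end primers for the tRNA-Asp(GTC) chop (no dCAPS base)."""
    converted = bs_convert_template(ASP_GTC_TEMPLATE, set())
    fwd = DCAPSPrimer("AspF", converted[:20])
    rev = DCAPSPrimer("AspR", reverse_complement(converted[-20:]))
    return fwd, rev


def asp_chop_assay() -> AssayReport:
    """HpyCH4IV chop of the 72 bp tRNA-Asp(GTC) amplicon at C38."""
    fwd, rev = asp_chop_primers()
    return assay_report(ASP_GTC_TEMPLATE, ASP_C38_POSITION, HPYCH4IV, fwd, rev)


def rrna_dcaps_primers(with_mismatch: bool = True) -> tuple[DCAPSPrimer, DCAPSPrimer]:
    """dCAPS primer pair for the 25S-like window.

    The forward primer spans window positions 1-32 of the converted
    template; with ``with_mismatch`` it carries G at position four from the
    3' end (window position 29), completing GANTC only over a
    methylation-protected C at position 33.
    """
    converted = bs_convert_template(RRNA_TEMPLATE, set())
    fwd_seq = list(converted[:32])
    mismatches: frozenset[int] = frozenset()
    if with_mismatch:
        fwd_seq[28] = "G"
        mismatches = frozenset({4})
    fwd = DCAPSPrimer("25S_rRNA_F", "".join(fwd_seq), mismatches)
    rev = DCAPSPrimer("25S_rRNA_R", reverse_complement(converted[-20:]))
    return fwd, rev


def rrna_dcaps_assay(with_mismatch: bool = True) -> AssayReport:
    """HinfI dCAPS digest of the 155 bp rRNA amplicon at the diagnostic C."""
    fwd, rev = rrna_dcaps_primers(with_mismatch)
    return assay_report(RRNA_TEMPLATE, RRNA_SITE_POSITION, HINFI, fwd, rev)
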
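"""In-silico methyl-chop PCR and dCAPS restriction digest prediction.

After bisulfite conversion, a methylated cytosine survives as C while an
unmethylated one reads T, so conversion can create or destroy restriction
sites in a methylation-dependent way. A methyl-chop assay PCR-amplifies the
converted template and digests the product: cut versus uncut reports the
methylation state of the diagnostic cytosine. Where the site context does
not form a recognition site on its own, a dCAPS primer carrying a
deliberate mismatch completes the site only for one conversion outcome.

PCR is modeled deterministically: primers must anneal uniquely within a
mismatch tolerance (none in the 3'-terminal two bases) and their bases —
including dCAPS mismatches — overwrite the template within the primer
footprints, as amplification incorporates them into every product molecule.
"""

from __future__ import annotations

from dataclasses import dataclass

from rbsmeth.errors import AssayError, ValidationError
from rbsmeth.seqtools import c_positions, find_iupac, reverse_complement, validate_dna


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease: IUPAC recognition and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValidationError("cut_offset outside the recognition site")

    @property
    def palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition


HPYCH4IV = Enzyme("HpyCH4IV", "ACGT", 1)  # A^CGT
HINFI = Enzyme("HinfI", "GANTC", 1)  # G^ANTC


@dataclass(frozen=True)
class DCAPSPrimer:
    """A PCR primer, optionally carrying dCAPS mismatches.

    ``mismatch_positions`` count from the 3' end (1 = terminal base) and
    annotate deliberate mismatches against the intended template.
    """

    name: str
    sequence: str
    mismatch_positions: frozenset[int] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "sequence", validate_dna(self.sequence, what=f"primer {self.name}"))
        if any(not 1 <= p <= len(self.sequence) for p in self.mismatch_positions):
            raise ValidationError(f"primer {self.name}: mismatch position outside primer")


@dataclass(frozen=True)
class DigestPrediction:
    """Predicted fragment pattern of one amplicon under one methylation state."""

    amplicon_length: int
    methylation_state: tuple[tuple[int, str], ...]
    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]

    @property
    def digested(self) -> bool:
        return len(self.cut_positions) > 0


@dataclass(frozen=True)
class AssayReport:
    """Both-state digest predictions and the informativeness verdict."""

    site_position: int
    enzyme: Enzyme
    methylated: DigestPrediction
    unmethylated: DigestPrediction

    @property
    def informative(self) -> bool:
        return self.methylated.fragment_lengths != self.unmethylated.fragment_lengths


def bs_convert_template(sequence: str, methylated_positions) -> str:
    """Bisulfite-convert a template: unmethylated C -> T, methylated C kept."""
    seq = validate_dna(sequence, what="template")
    protected = set(methylated_positions)
    cs = set(c_positions(seq))
    bad = protected - cs
    if bad:
        raise ValidationError(f"methylated positions are not cytosines: {sorted(bad)}")
    return "".join(
        "C" if (base == "C" and i + 1 in protected) else ("T" if base == "C" else base)
        for i, base in enumerate(seq)
    )


def _anneal_sites(primer_on_top: str, template: str, max_mismatch: int, three_prime_left: bool) -> list[int]:
    """0-based starts where a primer (already in top-strand orientation)
    anneals; the 3'-terminal two bases must match exactly."""
    plen = len(primer_on_top)
    sites = []
    for start in range(len(template) - plen + 1):
        window = template[start : start + plen]
        mm_positions = [i for i in range(plen) if primer_on_top[i] != window[i]]
        if len(mm_positions) > max_mismatch:
            continue
        terminal = range(0, 2) if three_prime_left else range(plen - 2, plen)
        if any(i in terminal for i in mm_positions):
            continue
        sites.append(start)
    return sites


def build_amplicon(
    template: str,
    fwd_primer: DCAPSPrimer,
    rev_primer: DCAPSPrimer,
    max_primer_mismatch: int = 2,
) -> tuple[str, int]:
    """Extract the PCR product from a (converted) single-stranded template.

    Returns ``(amplicon, start)`` where ``start`` is the 1-based template
    position of the amplicon's first base. Primer bases overwrite template
    bases within the primer footprints. Raises when a primer fails to
    anneal or anneals at multiple sites.
    """
    template = validate_dna(template, what="template")
    fwd_sites = _anneal_sites(fwd_primer.sequence, template, max_primer_mismatch, three_prime_left=False)
    rev_on_top = reverse_complement(rev_primer.sequence)
    rev_sites = _anneal_sites(rev_on_top, template, max_primer_mismatch, three_prime_left=True)
    for name, sites in ((fwd_primer.name, fwd_sites), (rev_primer.name, rev_sites)):
        if not sites:
            raise AssayError(f"primer {name} does not anneal to the template")
        if len(sites) > 1:
            raise AssayError(f"primer {name} anneals at multiple sites: {sites}")
    fwd_start = fwd_sites[0]
    rev_end = rev_sites[0] + len(rev_on_top)
    if rev_sites[0] < fwd_start + len(fwd_primer.sequence):
        raise AssayError("primer footprints overlap or are inverted")
    amplicon = list(template[fwd_start:rev_end])
    amplicon[: len(fwd_primer.sequence)] = fwd_primer.sequence
    amplicon[len(amplicon) - len(rev_on_top) :] = rev_on_top
    return "".join(amplicon), fwd_start + 1


def digest(amplicon: str, enzyme: Enzyme, methylation_state: dict[int, str] | None = None) -> DigestPrediction:
    """Cut an amplicon at every recognition-site match.

    Matches are found on the top strand; for non-palindromic recognition
    sequences the reverse-complement pattern is also scanned (a
    double-stranded PCR product presents the site on either strand) with
    the cut mirrored within the site. Fragment lengths are reported sorted
    ascending and always sum to the amplicon length.
    """
    amplicon = validate_dna(amplicon, what="amplicon")
    if not amplicon:
        raise ValidationError("amplicon is empty")
    cuts: set[int] = set()
    for start in find_iupac(enzyme.recognition, amplicon):
        cuts.add(start + enzyme.cut_offset)
    if not enzyme.palindromic:
        rc = reverse_complement(enzyme.recognition)
        for start in find_iupac(rc, amplicon):
            cuts.add(start + len(rc) - enzyme.cut_offset)
    cut_list = tuple(sorted(c for c in cuts if 0 < c < len(amplicon)))
    bounds = (0,) + cut_list + (len(amplicon),)
    fragments = tuple(sorted(b - a for a, b in zip(bounds, bounds[1:])))
    return DigestPrediction(
        amplicon_length=len(amplicon),
        methylation_state=tuple(sorted((methylation_state or {}).items())),
        cut_positions=cut_list,
        fragment_lengths=fragments,
    )


def assay_report(
    template: str,
    site_position: int,
    enzyme: Enzyme,
    fwd_primer: DCAPSPrimer,
    rev_primer: DCAPSPrimer,
    other_methylated: frozenset[int] = frozenset(),
) -> AssayReport:
    """Predict the digest under both methylation states of one site.

    The template is the unconverted sense sequence; it is bisulfite
    converted with the diagnostic site methylated and unmethylated in turn,
    amplified, and digested. The assay is informative when the two fragment
    patterns differ.
    """
    template = validate_dna(template, what="template")
    if not (1 <= site_position <= len(template)) or template[site_position - 1] != "C":
        raise ValidationError(f"site position {site_position} is not a cytosine of the template")
    predictions = {}
    for state, protected in (("methylated", {site_position}), ("unmethylated", set())):
        converted = bs_convert_template(template, protected | set(other_methylated))
        amplicon, start = build_amplicon(converted, fwd_primer, rev_primer)
        if not start <= site_position <= start + len(amplicon) - 1:
            raise AssayError(
                f"site {site_position} lies outside the amplicon ({start}..{start + len(amplicon) - 1})"
            )
        state_map = {site_position: state}
        predictions[state] = digest(amplicon, enzyme, state_map)
    return AssayReport(
        site_position=site_position,
        enzyme=enzyme,
        methylated=predictions["methylated"],
        unmethylated=predictions["unmethylated"],
    )


def render_gel(report: AssayReport, lane_width: int = 40) -> str:
    """ASCII virtual gel: one lane per state, bands positioned by size."""
    sizes = sorted(
        set(report.methylated.fragment_lengths) | set(report.unmethylated.fragment_lengths),
        reverse=True,
    )
    lines = [f"{'size':>6}  {'methylated':^12} {'unmethylated':^12}"]
    for size in sizes:
        m = "======" if size in report.methylated.fragment_lengths else "      "
        u = "======" if size in report.unmethylated.fragment_lengths else "      "
        lines.append(f"{size:>4}bp  {m:^12} {u:^12}")
    verdict = "informative" if report.informative else "uninformative"
    lines.append(f"assay: {verdict} ({report.enzyme.name})")
    return "\n".join(lines)
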
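"""Per-cytosine methylation calling from three-letter alignments.

Percentage methylation at a reference cytosine is the number of mapped
cytosines divided by the combined number of mapped cytosines and thymines
(other bases are sequencing noise and excluded from the denominator).
Candidate m5C sites require at least ``min_coverage`` informative reads
(default 5) and at least ``min_methylation`` (default 20%); libraries must
first pass the spike-in conversion gate (>= 98% aggregate conversion over
the control's cytosines). Sites passing the thresholds are candidate m5C
sites: other bisulfite-resistant cytosine modifications are
indistinguishable by this assay.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace

import pandas as pd
from scipy.stats import binomtest

from rbsmeth.align import Alignment
from rbsmeth.errors import AlignmentError, QCError, ValidationError

DEFAULT_MIN_COVERAGE = 5
DEFAULT_MIN_METHYLATION = 0.20
DEFAULT_MIN_CONVERSION = 0.98
DEFAULT_REDUCED_MARGIN = 0.20

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
NO_CALL = "no_call"


@dataclass
class SitePileup:
    """Fractional C/T/other counts at one reference cytosine.

    Counts are fractional because a read ambiguous between k references
    contributes 1/k to each co-champion's pileup.
    """

    reference_id: str
    position: int
    n_C: float = 0.0
    n_T: float = 0.0
    n_other: float = 0.0

    @property
    def coverage(self) -> float:
        return self.n_C + self.n_T

    @property
    def methylation(self) -> float | None:
        """C / (C + T); None when no informative read covers the site."""
        return percent_methylation(self.n_C, self.n_T)


@dataclass
class SiteCall:
    """A thresholded per-site decision with the thresholds that produced it."""

    reference_id: str
    position: int
    n_C: float
    n_T: float
    n_other: float
    status: str
    min_coverage: float
    min_methylation: float
    p_value: float | None = None

    @property
    def coverage(self) -> float:
        return self.n_C + self.n_T

    @property
    def methylation(self) -> float | None:
        return percent_methylation(self.n_C, self.n_T)


@dataclass
class ConversionQC:
    """Spike-in conversion efficiency summary for one library."""

    control_id: str
    per_site_conversion: dict[int, float]
    global_conversion: float
    n_control_cytosines: int
    threshold: float
    passed: bool


def percent_methylation(n_C: float, n_T: float) -> float | None:
    """Mapped C over mapped C + mapped T; None (undefined) at zero coverage."""
    total = n_C + n_T
    if total <= 0:
        return None
    return n_C / total


def tally_pileup(
    alignments: Mapping[str, Sequence[Alignment]],
    reads: Mapping[str, str] | Iterable[tuple[str, str]],
    refset,
) -> list[SitePileup]:
    """Tally per-cytosine pileups from champion alignments.

    ``alignments`` maps read_id -> champion alignments (e.g. from
    :func:`rbsmeth.align.align_reads`); ``reads`` supplies the *original*
    (unconverted) read sequences; ``refset`` are the converted references
    whose ``c_positions`` define where to look. Every cytosine position of
    every reference is reported, including uncovered ones (coverage 0), so
    downstream rendering can distinguish "no data" from "unmethylated".
    """
    if not isinstance(reads, Mapping):
        reads = dict(reads)
    ref_index = {ref.source_id: ref for ref in refset}
    pileups: dict[tuple[str, int], SitePileup] = {}
    for ref in refset:
        for pos in ref.c_positions:
            pileups[(ref.source_id, pos)] = SitePileup(ref.source_id, pos)

    for read_id, champs in alignments.items():
        if not champs:
            continue
        seq = reads[read_id].upper()
        for aln in champs:
            ref = ref_index.get(aln.reference_id)
            if ref is None:
                raise AlignmentError(f"alignment to unknown reference {aln.reference_id!r}")
            weight = aln.weight
            end = aln.start + len(seq) - 1
            for pos in ref.c_positions:
                if pos < aln.start:
                    continue
                if pos > end:
                    break
                base = seq[pos - aln.start]
                pileup = pileups[(ref.source_id, pos)]
                if base == "C":
                    pileup.n_C += weight
                elif base == "T":
                    pileup.n_T += weight
                else:
                    pileup.n_other += weight
    return [pileups[key] for key in sorted(pileups)]


def qc_conversion(
    control_pileups: Sequence[SitePileup],
    min_conversion: float = DEFAULT_MIN_CONVERSION,
    control_id: str | None = None,
) -> ConversionQC:
    """Aggregate conversion efficiency over the spike-in control's cytosines.

    Conversion at a control cytosine is T/(C+T); the library-level rate is
    the pooled ratio over all control cytosines. A library passes when the
    pooled rate reaches ``min_conversion`` (default 98%). Per-cytosine
    rates are also reported for inspection.
    """
    covered = [p for p in control_pileups if p.coverage > 0]
    if not covered:
        raise QCError("no covered control cytosines: conversion efficiency unmeasurable")
    if control_id is None:
        control_id = covered[0].reference_id
    per_site = {p.position: p.n_T / p.coverage for p in covered}
    total_t = sum(p.n_T for p in covered)
    total = sum(p.coverage for p in covered)
    global_conversion = total_t / total
    return ConversionQC(
        control_id=control_id,
        per_site_conversion=per_site,
        global_conversion=global_conversion,
        n_control_cytosines=len(control_pileups),
        threshold=min_conversion,
        passed=global_conversion >= min_conversion,
    )


def call_sites(
    pileups: Sequence[SitePileup],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_methylation: float = DEFAULT_MIN_METHYLATION,
    qc: ConversionQC | None = None,
) -> list[SiteCall]:
    """Apply the coverage / methylation thresholds to pileups.

    Raises :class:`QCError` when a failed conversion QC is supplied: calls
    from an under-converted library are invalid. Boundary rule: a site at
    exactly ``min_methylation`` (and sufficient coverage) is methylated.
    """
    if qc is not None and not qc.passed:
        raise QCError(
            f"library failed conversion QC ({qc.global_conversion:.4f} < {qc.threshold})"
        )
    calls = []
    for pileup in pileups:
        if pileup.coverage < min_coverage:
            status = NO_CALL
        elif pileup.methylation >= min_methylation:
            status = METHYLATED
        else:
            status = UNMETHYLATED
        calls.append(
            SiteCall(
                reference_id=pileup.reference_id,
                position=pileup.position,
                n_C=pileup.n_C,
                n_T=pileup.n_T,
                n_other=pileup.n_other,
                status=status,
                min_coverage=min_coverage,
                min_methylation=min_methylation,
            )
        )
    return calls


def annotate_binomial(calls: Sequence[SiteCall], null_rate: float) -> list[SiteCall]:
    """Optional annotation: one-sided binomial test of n_C against the
    conversion-failure null (rate ``1 - conversion_efficiency``).

    Fractional counts are rounded to the nearest integer for the test.
    """
    if not 0 <= null_rate <= 1:
        raise ValidationError("null_rate must be in [0, 1]")
    annotated = []
    for call in calls:
        total = round(call.coverage)
        if total <= 0:
            annotated.append(replace(call, p_value=None))
            continue
        k = min(round(call.n_C), total)
        p = binomtest(k, total, null_rate, alternative="greater").pvalue
        annotated.append(replace(call, p_value=float(p)))
    return annotated


def global_cytosine_abundance(
    alignments: Mapping[str, Sequence[Alignment]],
    reads: Mapping[str, str] | Iterable[tuple[str, str]],
    exclude_references: Iterable[str] = (),
) -> float:
    """Fraction of C among aligned read bases over endogenous references.

    Spike-in control references are excluded via ``exclude_references``. In
    a well-converted bisulfite library this is far below the ~22% cytosine
    composition of unconverted RNA, since only methylated or
    conversion-escaped cytosines remain.
    """
    if not isinstance(reads, Mapping):
        reads = dict(reads)
    excluded = set(exclude_references)
    total = 0.0
    n_c = 0.0
    for read_id, champs in alignments.items():
        for aln in champs:
            if aln.reference_id in excluded:
                continue
            seq = reads[read_id].upper()
            total += aln.weight * len(seq)
            n_c += aln.weight * seq.count("C")
    if total == 0:
        raise ValidationError("no aligned bases over endogenous references")
    return n_c / total


LOST = "lost"
REDUCED = "reduced"
UNCHANGED = "unchanged"


def differential_sites(
    calls_wt: Sequence[SiteCall],
    calls_mutant: Sequence[SiteCall],
    reduced_margin: float = DEFAULT_REDUCED_MARGIN,
) -> pd.DataFrame:
    """Compare site calls between genotypes (e.g. wild type vs an RMTase mutant).

    Per comparable site: ``lost`` when the wild type is methylated and the
    mutant drops below the calling threshold; ``reduced`` when both are
    methylated but the mutant fraction is lower by at least
    ``reduced_margin`` (absolute); ``unchanged`` otherwise. Sites that are
    no_call in either genotype are excluded. Both call sets must cover the
    same reference cytosines.
    """
    wt = {(c.reference_id, c.position): c for c in calls_wt}
    mut = {(c.reference_id, c.position): c for c in calls_mutant}
    if set(wt) != set(mut):
        raise ValidationError("genotypes were called on different reference sets")
    rows = []
    for key in sorted(wt):
        a, b = wt[key], mut[key]
        if a.status == NO_CALL or b.status == NO_CALL:
            continue
        if a.status == METHYLATED:
            if b.status != METHYLATED:
                change = LOST
            elif a.methylation - b.methylation >= reduced_margin:
                change = REDUCED
            else:
                change = UNCHANGED
        else:
            change = UNCHANGED
        rows.append(
            {
                "reference_id": key[0],
                "position": key[1],
                "wt_methylation": a.methylation,
                "mutant_methylation": b.methylation,
                "wt_status": a.status,
                "mutant_status": b.status,
                "change": change,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "reference_id",
            "position",
            "wt_methylation",
            "mutant_methylation",
            "wt_status",
            "mutant_status",
            "change",
        ],
    )
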
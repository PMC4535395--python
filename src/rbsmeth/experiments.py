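"""Reusable in-silico validation experiments.

These run the full stack (simulate -> align -> tally -> call) under
controlled conditions and summarise how well the pipeline recovers the
simulator's ground truth: per-site methylation recovery accuracy, the
spike-in conversion-QC gate, and convergence of observed methylation to its
closed-form expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rbsmeth.align import ReadAligner
from rbsmeth.calling import (
    METHYLATED,
    ConversionQC,
    call_sites,
    qc_conversion,
    tally_pileup,
)
from rbsmeth.reference import in_silico_convert
from rbsmeth.simulate import (
    SimulationConfig,
    expected_observed_methylation,
    make_spikein_with_c_count,
    simulate_bisulfite_reads,
)

METHYLATION_LEVELS = (0.0, 0.2, 0.5, 0.8, 1.0)


def random_reference_with_c_count(rng: np.random.Generator, length: int, n_c: int) -> str:
    """Random DNA with exactly ``n_c`` cytosines."""
    bases = rng.choice(list("AGT"), size=length)
    bases[rng.choice(length, size=n_c, replace=False)] = "C"
    return "".join(bases)


@dataclass(frozen=True)
class RecoveryResult:
    n_sites: int
    n_evaluated: int
    mean_absolute_error: float
    mean_coverage: float
    false_positive_methylated_at_zero: int
    n_zero_sites: int


def parameter_recovery(
    seed: int,
    n_references: int = 50,
    c_per_reference: int = 20,
    target_depth: int = 100,
    conversion_efficiency: float = 0.99,
    over_conversion: float = 0.01,
    levels: tuple[float, ...] = METHYLATION_LEVELS,
) -> RecoveryResult:
    """Simulate ~``n_references * c_per_reference`` sites at ~``target_depth``
    coverage, run the full pipeline, and score methylation recovery.

    True methylation fractions cycle through ``levels``. Returns the mean
    absolute error of recovered methylation over evaluable sites and the
    number of true-zero sites wrongly called methylated under the
    5-read / 20% rule.
    """
    rng = np.random.default_rng(seed)
    length = 80
    refs = {
        f"synt{i:03d}": random_reference_with_c_count(rng, length, c_per_reference)
        for i in range(n_references)
    }
    truth_map: dict[tuple[str, int], float] = {}
    level_cycle = list(levels)
    k = 0
    for rid, seq in refs.items():
        for pos0, base in enumerate(seq):
            if base == "C":
                truth_map[(rid, pos0 + 1)] = level_cycle[k % len(level_cycle)]
                k += 1

    mean_read_len = (65 + length) / 2
    n_reads = int(round(n_references * target_depth * length / mean_read_len))
    config = SimulationConfig(
        seed=seed + 1,
        references=tuple((rid, 1.0) for rid in refs),
        methylation_map=truth_map,
        conversion_efficiency=conversion_efficiency,
        over_conversion=over_conversion,
        read_length_range=(65, length),
        n_reads=n_reads,
    )
    reads, _ = simulate_bisulfite_reads(config, refs)
    refset = [in_silico_convert(rid, seq) for rid, seq in refs.items()]
    aligner = ReadAligner(refset)
    alignments = {rid: aligner.align(seq, rid) for rid, seq in reads}
    pileups = tally_pileup(alignments, dict(reads), refset)
    calls = call_sites(pileups)

    errors = []
    coverages = []
    false_positives = 0
    n_zero = 0
    for call in calls:
        true_m = truth_map[(call.reference_id, call.position)]
        if true_m == 0.0:
            n_zero += 1
            if call.status == METHYLATED:
                false_positives += 1
        if call.methylation is None or call.coverage < 5:
            continue
        errors.append(abs(call.methylation - true_m))
        coverages.append(call.coverage)
    return RecoveryResult(
        n_sites=len(calls),
        n_evaluated=len(errors),
        mean_absolute_error=float(np.mean(errors)),
        mean_coverage=float(np.mean(coverages)),
        false_positive_methylated_at_zero=false_positives,
        n_zero_sites=n_zero,
    )


def spikein_qc_experiment(
    seed: int,
    conversion_efficiency: float,
    n_reads: int = 1000,
    min_conversion: float = 0.98,
) -> tuple[ConversionQC, float]:
    """Simulate a spike-in-only library and run the conversion gate.

    The control mimics the study geometry: a 1068-nt transcript carrying
    178 cytosines; at the default read count the pooled control pileup
    exceeds 10^4 cytosine observations. Returns the QC record and the
    pooled number of cytosine observations behind it.
    """
    control = make_spikein_with_c_count(length=1068, n_cytosines=178, seed=seed)
    config = SimulationConfig(
        seed=seed + 1,
        references=(),
        conversion_efficiency=conversion_efficiency,
        read_length_range=(65, 95),
        n_reads=n_reads,
        spikein_fraction=1.0,
    )
    reads, _ = simulate_bisulfite_reads(config, {}, control)
    refset = [in_silico_convert(control.control_id, control.sequence)]
    aligner = ReadAligner(refset)
    alignments = {rid: aligner.align(seq, rid) for rid, seq in reads}
    pileups = tally_pileup(alignments, dict(reads), refset)
    total_observations = sum(p.coverage for p in pileups)
    return qc_conversion(pileups, min_conversion, control.control_id), total_observations


def closed_form_grid(
    seed: int,
    depth: int = 10_000,
    m_values: tuple[float, ...] = (0.0, 0.5, 1.0),
    e_values: tuple[float, ...] = (0.95, 0.99),
    o_values: tuple[float, ...] = (0.0, 0.05),
) -> list[dict]:
    """Empirical vs closed-form observed methylation over an (m, e, o) grid.

    A single-cytosine reference is sequenced to ``depth`` covering reads
    per combination; the observed C/(C+T) is compared with
    ``m(1-o) + (1-m)(1-e)``. Returns one row per combination with the
    empirical rate, expectation, depth and binomial standard error.
    """
    base_rng = np.random.default_rng(seed)
    seq = list(base_rng.choice(list("AGT"), size=70))
    seq[34] = "C"
    ref = {"one-site": "".join(seq)}
    rows = []
    combo_seed = seed
    for m in m_values:
        for e in e_values:
            for o in o_values:
                combo_seed += 1
                config = SimulationConfig(
                    seed=combo_seed,
                    references=(("one-site", 1.0),),
                    methylation_map={("one-site", 35): m},
                    conversion_efficiency=e,
                    over_conversion=o,
                    seq_error_rate=0.0,
                    read_length_range=(65, 70),
                    n_reads=depth,
                )
                _, truth = simulate_bisulfite_reads(config, ref)
                n_c, n_t = truth.site_counts("one-site", 35)
                total = n_c + n_t
                expected = expected_observed_methylation(m, e, o)
                rows.append(
                    {
                        "m": m,
                        "e": e,
                        "o": o,
                        "depth": total,
                        "observed": n_c / total,
                        "expected": expected,
                        "se": float(np.sqrt(expected * (1 - expected) / total)),
                    }
                )
    return rows
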
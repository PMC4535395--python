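"""Synthetic RBS-seq / RNA-seq read generation with known ground truth.

The generator emulates the structure of a stranded, single-end small-RNA
bisulfite library: short reads (65-95 nt, matching gel size selection of the
tRNA fraction) drawn from a weighted panel of tRNA/rRNA references plus a
methylation-free in-vitro-transcribed spike-in control, with per-site true
methylation fractions, incomplete bisulfite conversion, over-conversion of
methylated cytosines, and uniform substitution sequencing error.

Per-cytosine channel, for true methylation fraction ``m``, conversion
efficiency ``e`` and over-conversion ``o``:

* a methylated C survives as C with probability ``1 - o``;
* an unmethylated C deaminates to T with probability ``e``;

so the expected observed methylation at a site is ``m(1-o) + (1-m)(1-e)``.

Identical seed and configuration give byte-identical output (reproducibility
contract); all randomness flows from one ``numpy`` generator.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rbsmeth.errors import ValidationError
from rbsmeth.seqtools import validate_dna

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated library.

    Defaults mirror a well-behaved bisulfite library: 99% conversion of
    unmethylated cytosines (above the 98% QC floor), 1% over-conversion of
    methylated cytosines, 0.1% substitution error, 65-95 nt reads.
    """

    seed: int
    references: tuple[tuple[str, float], ...]
    methylation_map: Mapping[tuple[str, int], float] = field(default_factory=dict)
    conversion_efficiency: float = 0.99
    over_conversion: float = 0.01
    seq_error_rate: float = 0.001
    read_length_range: tuple[int, int] = (65, 95)
    n_reads: int = 1000
    spikein_fraction: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "references", tuple((r, float(w)) for r, w in self.references))
        for name in ("conversion_efficiency", "over_conversion", "seq_error_rate", "spikein_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        for (_, pos), m in self.methylation_map.items():
            if not 0.0 <= m <= 1.0:
                raise ValidationError(f"methylation fraction at position {pos} out of [0, 1]")
        lo, hi = self.read_length_range
        if lo > hi:
            raise ValidationError("read_length_range min exceeds max")
        if self.n_reads < 0:
            raise ValidationError("n_reads must be >= 0")
        if any(w < 0 for _, w in self.references):
            raise ValidationError("abundance weights must be non-negative")


@dataclass(frozen=True)
class SpikeInControl:
    """A methylation-free conversion control (in-vitro transcript analogue).

    Every cytosine is unmethylated by construction, so after bisulfite
    treatment any residual C on the control measures conversion failure.
    """

    control_id: str
    sequence: str
    n_cytosines: int

    def __post_init__(self):
        seq = validate_dna(self.sequence, what=f"control {self.control_id}")
        object.__setattr__(self, "sequence", seq)
        if self.n_cytosines != seq.count("C"):
            raise ValidationError("n_cytosines does not match the sequence")


@dataclass
class TruthTable:
    """Ground truth for a simulated library.

    ``per_read`` has one row per emitted read (read_id, source, start,
    length, outcomes) where ``outcomes`` encodes, per read position:
    ``.`` non-cytosine source base, ``M`` methylated C retained as C,
    ``m`` methylated C over-converted to T, ``U`` unmethylated C converted
    to T, ``u`` unmethylated C that escaped conversion (reads as C).
    ``per_site`` has one row per (reference, cytosine position) with the
    true methylation fraction.
    """

    per_read: pd.DataFrame
    per_site: pd.DataFrame

    def site_counts(self, reference_id: str, position: int) -> tuple[float, float]:
        """(n_C, n_T) at a site from true read placements (no alignment).

        Counts pre-error conversion outcomes, so it isolates the
        conversion channel of the simulator.
        """
        n_c = n_t = 0
        for row in self.per_read.itertuples():
            if row.source != reference_id:
                continue
            offset = position - row.start
            if not 0 <= offset < row.length:
                continue
            outcome = row.outcomes[offset]
            if outcome in "Mu":
                n_c += 1
            elif outcome in "mU":
                n_t += 1
        return float(n_c), float(n_t)


def make_spikein(length: int, gc_fraction: float, seed: int, control_id: str = "RLuc-like") -> SpikeInControl:
    """Generate a random methylation-free control sequence.

    ``length`` must be >= 100 so the control carries enough cytosines for a
    stable conversion-efficiency estimate.
    """
    if length < 100:
        raise ValidationError("spike-in length must be >= 100 nt")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValidationError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2])
    seq = b"".join(rng.choice(_BASES, size=length, p=p)).decode()
    return SpikeInControl(control_id=control_id, sequence=seq, n_cytosines=seq.count("C"))


def make_spikein_with_c_count(
    length: int,
    n_cytosines: int,
    seed: int,
    gc_fraction: float | None = None,
    max_tries: int = 10_000,
    control_id: str = "RLuc-like",
) -> SpikeInControl:
    """Rejection-sample seeds until the control has exactly ``n_cytosines`` Cs.

    Used to build a control mimicking the study's 178-cytosine transcript.
    """
    if gc_fraction is None:
        gc_fraction = min(1.0, 2.0 * n_cytosines / length)
    for attempt in range(max_tries):
        control = make_spikein(length, gc_fraction, seed + attempt, control_id=control_id)
        if control.n_cytosines == n_cytosines:
            return control
    raise ValidationError(
        f"could not reach {n_cytosines} cytosines at length {length} in {max_tries} tries"
    )


def _normalise_panel(refs) -> dict[str, str]:
    if isinstance(refs, Mapping):
        return {rid: validate_dna(seq, what=rid) for rid, seq in refs.items()}
    return {rid: validate_dna(seq, what=rid) for rid, seq in refs}


def _validate_methylation_map(config: SimulationConfig, panel: Mapping[str, str], control_id: str | None):
    for (rid, pos), _ in config.methylation_map.items():
        if control_id is not None and rid == control_id:
            raise ValidationError("spike-in control cytosines cannot appear in the methylation map")
        if rid not in panel:
            raise ValidationError(f"methylation map references unknown reference {rid!r}")
        seq = panel[rid]
        if not 1 <= pos <= len(seq) or seq[pos - 1] != "C":
            raise ValidationError(f"position {pos} of {rid} is not a cytosine")


def _simulate(
    config: SimulationConfig,
    refs,
    control: SpikeInControl | None,
    *,
    bisulfite: bool,
) -> tuple[list[tuple[str, str]], TruthTable]:
    panel = _normalise_panel(refs)
    control_id = control.control_id if control is not None else None
    _validate_methylation_map(config, panel, control_id)

    weight_for = dict(config.references)
    missing = [rid for rid in panel if rid not in weight_for]
    if missing:
        raise ValidationError(f"no abundance weight for references {missing}")
    sources = list(panel.items())
    weights = np.array([weight_for[rid] for rid, _ in sources], dtype=float)
    if weights.sum() <= 0 and config.n_reads > 0 and (control is None or config.spikein_fraction < 1):
        raise ValidationError("all abundance weights are zero")
    probs = weights / weights.sum() if weights.sum() > 0 else weights
    if control is not None and config.spikein_fraction > 0:
        sources = sources + [(control.control_id, control.sequence)]
        probs = np.append(probs * (1 - config.spikein_fraction), config.spikein_fraction)

    rng = np.random.default_rng(config.seed)
    lo, hi = config.read_length_range
    e = config.conversion_efficiency
    o = config.over_conversion

    reads: list[tuple[str, str]] = []
    truth_rows = []
    for i in range(config.n_reads):
        src_idx = int(rng.choice(len(sources), p=probs))
        src_id, src_seq = sources[src_idx]
        length = min(int(rng.integers(lo, hi + 1)), len(src_seq))
        start0 = int(rng.integers(0, len(src_seq) - length + 1))
        fragment = src_seq[start0 : start0 + length]

        bases = list(fragment)
        outcomes = ["."] * length
        if bisulfite:
            for j, base in enumerate(fragment):
                if base != "C":
                    continue
                m = config.methylation_map.get((src_id, start0 + j + 1), 0.0) if src_id != control_id else 0.0
                if rng.random() < m:
                    if rng.random() < 1 - o:
                        outcomes[j] = "M"  # methylated, protected -> C
                    else:
                        bases[j] = "T"
                        outcomes[j] = "m"  # methylated, over-converted
                else:
                    if rng.random() < e:
                        bases[j] = "T"
                        outcomes[j] = "U"  # converted
                    else:
                        outcomes[j] = "u"  # conversion failure -> residual C

        if config.seq_error_rate > 0:
            err = rng.random(length) < config.seq_error_rate
            for j in np.flatnonzero(err):
                current = bases[j]
                choices = [b for b in "ACGT" if b != current]
                bases[j] = choices[int(rng.integers(0, len(choices)))]

        read_id = f"r{i:06d}"
        reads.append((read_id, "".join(bases)))
        truth_rows.append((read_id, src_id, start0 + 1, length, "".join(outcomes)))

    per_read = pd.DataFrame(truth_rows, columns=["read_id", "source", "start", "length", "outcomes"])
    site_rows = [
        (rid, pos, frac) for (rid, pos), frac in sorted(config.methylation_map.items())
    ]
    per_site = pd.DataFrame(site_rows, columns=["reference_id", "position", "true_methylation"])
    return reads, TruthTable(per_read=per_read, per_site=per_site)


def simulate_bisulfite_reads(
    config: SimulationConfig,
    refs,
    control: SpikeInControl | None = None,
) -> tuple[list[tuple[str, str]], TruthTable]:
    """Simulate a stranded bisulfite (RBS-seq) library.

    ``refs`` is a mapping or sequence of ``(reference_id, sequence)`` with
    unconverted DNA sequences; conversion is applied per read. Returns
    ``(reads, truth)`` where reads are ``(read_id, sequence)`` pairs.
    """
    return _simulate(config, refs, control, bisulfite=True)


def simulate_rnaseq_reads(
    config: SimulationConfig,
    refs,
) -> tuple[list[tuple[str, str]], TruthTable]:
    """Simulate an ordinary (non-bisulfite) stranded RNA-seq library."""
    return _simulate(config, refs, None, bisulfite=False)


def expected_observed_methylation(m: float, e: float, o: float) -> float:
    """Closed-form expected C/(C+T) at a site: ``m(1-o) + (1-m)(1-e)``."""
    return m * (1 - o) + (1 - m) * (1 - e)


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    """Write reads as FASTQ with constant quality (the pipeline ignores quality)."""
    with open(path, "w") as handle:
        for read_id, seq in reads:
            handle.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    """Read a FASTQ file into ``(read_id, sequence)`` pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]
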
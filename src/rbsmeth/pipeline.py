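"""End-to-end orchestration: simulate/ingest -> align -> QC -> call -> report.

A run takes a configuration (thresholds, seed, sample sheet), produces one
directory with every stage's outputs, and records a provenance manifest
(package version, seed, configuration hash, output inventory). Re-running
with an identical configuration reproduces identical site tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import rbsmeth
from rbsmeth.align import ReadAligner
from rbsmeth.calling import (
    DEFAULT_MIN_CONVERSION,
    DEFAULT_MIN_COVERAGE,
    DEFAULT_MIN_METHYLATION,
    call_sites,
    differential_sites,
    global_cytosine_abundance,
    qc_conversion,
    tally_pileup,
)
from rbsmeth.conservation import build_conservation_table, class_counts, conservation_long_table
from rbsmeth.errors import QCError, RbsmethError, ValidationError
from rbsmeth.io import heatmap_matrix, write_fasta, write_sam, write_site_table
from rbsmeth.panel import StudyPanel, bundled_panel
from rbsmeth.reference import in_silico_convert
from rbsmeth.simulate import SimulationConfig, simulate_bisulfite_reads, write_fastq
from rbsmeth.structure import assign_trna_structure

log = logging.getLogger("rbsmeth")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and study conditions for one pipeline run."""

    seed: int = 0
    min_coverage: float = DEFAULT_MIN_COVERAGE
    min_methylation: float = DEFAULT_MIN_METHYLATION
    min_conversion: float = DEFAULT_MIN_CONVERSION
    max_mismatch: int = 2
    identity: float = 0.95
    n_reads: int = 4000
    spikein_fraction: float = 0.1
    conversion_efficiency: float = 0.99
    over_conversion: float = 0.01
    seq_error_rate: float = 0.001
    genotypes: tuple[str, ...] = ("wild_type", "mutant")

    def __post_init__(self):
        for name in ("min_methylation", "min_conversion", "spikein_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} out of [0, 1]")
        if self.min_coverage < 0 or self.max_mismatch < 0 or self.n_reads < 0:
            raise ValidationError("counts must be non-negative")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "min_coverage": self.min_coverage,
            "min_methylation": self.min_methylation,
            "min_conversion": self.min_conversion,
            "max_mismatch": self.max_mismatch,
            "identity": self.identity,
            "n_reads": self.n_reads,
            "spikein_fraction": self.spikein_fraction,
            "conversion_efficiency": self.conversion_efficiency,
            "over_conversion": self.over_conversion,
            "seq_error_rate": self.seq_error_rate,
            "genotypes": list(self.genotypes),
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if "genotypes" in data:
            data["genotypes"] = tuple(data["genotypes"])
        return cls(**data)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir, panel: StudyPanel | None = None) -> dict:
    """Run the full synthetic-study pipeline into ``out_dir``.

    Stages: reference conversion, per-genotype bisulfite simulation,
    three-letter alignment, spike-in conversion QC (a failing genotype
    aborts the run naming the sample), site calling, structural labelling,
    differential report between the first genotype (reference genotype) and
    each other, cross-panel conservation table. Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    timings: dict[str, float] = {}
    panel = panel if panel is not None else bundled_panel(config.seed)

    def emit(relpath: str):
        outputs.append(relpath)
        return out / relpath

    t0 = time.time()
    # --- references ------------------------------------------------------
    converted = [in_silico_convert(rid, seq) for rid, seq in panel.references]
    converted_control = in_silico_convert(panel.control.control_id, panel.control.sequence)
    refset = converted + [converted_control]
    (out / "refs").mkdir(exist_ok=True)
    write_fasta(list(panel.references), emit("refs/consensus.fasta"))
    write_fasta([(r.source_id, r.converted_sequence) for r in refset], emit("refs/converted.fasta"))

    structural_labels: dict[tuple[str, int], int] = {}
    smap_rows = []
    for rid, seq in panel.references:
        smap = assign_trna_structure(seq, panel.anticodons[rid], rid)
        for idx, label in smap.mapping:
            structural_labels[(rid, idx)] = label
            smap_rows.append(f"{rid}\t{idx}\t{label}")
    with open(emit("refs/structural_map.tsv"), "w") as handle:
        handle.write("reference_id\tseq_index\tstructural_label\n")
        handle.write("\n".join(smap_rows) + "\n")
    timings["references"] = time.time() - t0

    # --- per-genotype simulate/align/call --------------------------------
    aligner = ReadAligner(refset, config.max_mismatch)
    calls_by_genotype = {}
    seqs_by_genotype = {}
    qc_summary = {}
    for g_idx, genotype in enumerate(config.genotypes):
        t0 = time.time()
        if genotype not in panel.methylation:
            raise ValidationError(f"panel has no methylation map for genotype {genotype!r}")
        sample_dir = out / "samples" / genotype
        sample_dir.mkdir(parents=True, exist_ok=True)
        sim = SimulationConfig(
            seed=config.seed * 1000 + g_idx,
            references=tuple((rid, 1.0) for rid, _ in panel.references),
            methylation_map=panel.methylation[genotype],
            conversion_efficiency=config.conversion_efficiency,
            over_conversion=config.over_conversion,
            seq_error_rate=config.seq_error_rate,
            read_length_range=(65, 72),
            n_reads=config.n_reads,
            spikein_fraction=config.spikein_fraction,
        )
        reads, _ = simulate_bisulfite_reads(sim, panel.reference_dict, panel.control)
        write_fastq(reads, emit(f"samples/{genotype}/reads.fastq"))
        read_map = dict(reads)
        alignments = {rid: aligner.align(seq, rid) for rid, seq in reads}
        write_sam(alignments, read_map, refset, emit(f"samples/{genotype}/aln.sam"))

        pileups = tally_pileup(alignments, read_map, refset)
        control_piles = [p for p in pileups if p.reference_id == panel.control.control_id]
        qc = qc_conversion(control_piles, config.min_conversion, panel.control.control_id)
        qc_summary[genotype] = {
            "global_conversion": qc.global_conversion,
            "passed": qc.passed,
            "n_control_cytosines": qc.n_control_cytosines,
        }
        if not qc.passed:
            raise QCError(
                f"stage=qc sample={genotype}: conversion "
                f"{qc.global_conversion:.4f} below {config.min_conversion}"
            )
        endogenous = [p for p in pileups if p.reference_id != panel.control.control_id]
        calls = call_sites(endogenous, config.min_coverage, config.min_methylation, qc=qc)
        calls_by_genotype[genotype] = calls
        seqs_by_genotype[genotype] = panel.reference_dict
        write_site_table(calls, emit(f"samples/{genotype}/sites.tsv"), structural_labels)
        qc_summary[genotype]["global_cytosine_abundance"] = global_cytosine_abundance(
            alignments, read_map, exclude_references={panel.control.control_id}
        )
        timings[f"sample:{genotype}"] = time.time() - t0
        log.info("sample %s: %d reads, conversion %.4f", genotype, len(reads), qc.global_conversion)

    with open(emit("qc.json"), "w") as handle:
        json.dump(qc_summary, handle, indent=2)

    # --- differential + heatmap ------------------------------------------
    t0 = time.time()
    reference_genotype = config.genotypes[0]
    for genotype in config.genotypes[1:]:
        diff = differential_sites(calls_by_genotype[reference_genotype], calls_by_genotype[genotype])
        diff.to_csv(emit(f"differential_{reference_genotype}_vs_{genotype}.tsv"), sep="\t", index=False)
    heatmap_matrix(calls_by_genotype).to_csv(emit("heatmap.tsv"), sep="\t", na_rep="NA")

    # --- conservation across panel members -------------------------------
    # The conservation machinery compares call sets at shared structural
    # coordinates; here the panel members are the genotypes of one species.
    for rid, seq in panel.references:
        smap = assign_trna_structure(seq, panel.anticodons[rid], rid)
        mapping = dict(smap.mapping)
        table = build_conservation_table(
            {g: [c for c in calls_by_genotype[g] if c.reference_id == rid] for g in config.genotypes},
            {g: mapping for g in config.genotypes},
            {g: seq for g in config.genotypes},
            rna_id=rid,
            min_methylation=config.min_methylation,
            min_classifiable=2,
        )
        if table:
            conservation_long_table(table).to_csv(
                emit(f"conservation_{rid}.tsv"), sep="\t", index=False, na_rep="NA"
            )
    timings["reports"] = time.time() - t0

    manifest = {
        "package": "rbsmeth",
        "version": rbsmeth.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "outputs": sorted(outputs),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with (out / "manifest.json").open("w") as handle:
        json.dump(manifest, handle, indent=2)
    with (out / "config.yaml").open("w") as handle:
        yaml.safe_dump(config.to_dict(), handle)
    return manifest
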
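"""File-format helpers: FASTA, sidecar TSV metadata, SAM, per-site tables."""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from rbsmeth.align import Alignment
from rbsmeth.calling import NO_CALL, SiteCall
from rbsmeth.errors import ValidationError
from rbsmeth.reference import ConvertedReference, TRNAGeneRecord


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path),
        "fasta",
    )


def read_trna_genes(fasta_path, meta_path) -> list[TRNAGeneRecord]:
    """Load tRNA genes from FASTA plus a sidecar TSV.

    The TSV carries columns gene_id, genome, aa, anticodon; keeping the
    annotation out of the FASTA headers avoids header-dialect parsing.
    """
    sequences = dict(read_fasta(fasta_path))
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"gene_id", "genome", "aa", "anticodon"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"tRNA metadata TSV missing columns: {sorted(missing)}")
    genes = []
    for row in meta.itertuples():
        if row.gene_id not in sequences:
            raise ValidationError(f"gene {row.gene_id} in metadata but not in FASTA")
        genes.append(
            TRNAGeneRecord(
                gene_id=row.gene_id,
                genome=row.genome,
                amino_acid=row.aa,
                anticodon=row.anticodon,
                sequence=sequences[row.gene_id],
            )
        )
    return genes


def write_consensus_manifest(consensuses, path) -> None:
    rows = [
        {
            "consensus_id": c.consensus_id,
            "genomes": ",".join(sorted(c.genomes)),
            "n_members": len(c.member_gene_ids),
            "length": len(c.sequence),
        }
        for c in consensuses
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SAM

def _sam_header(refset: Sequence[ConvertedReference]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref.source_id, "LN": ref.length} for ref in refset],
    }


def write_sam(
    alignments: Mapping[str, Sequence[Alignment]],
    reads: Mapping[str, str],
    refset: Sequence[ConvertedReference],
    path,
) -> None:
    """Write champion alignments as SAM.

    One record per co-champion; SEQ holds the original (unconverted) read
    bases, NM the three-letter mismatch count, XC the co-champion count
    (XC > 1 marks an ambiguous read).
    """
    header = pysam.AlignmentHeader.from_dict(_sam_header(refset))
    tid = {ref.source_id: i for i, ref in enumerate(refset)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read_id in sorted(alignments):
            for aln in alignments[read_id]:
                seq = reads[read_id]
                rec = pysam.AlignedSegment(header)
                rec.query_name = read_id
                rec.query_sequence = seq
                rec.flag = 0
                rec.reference_id = tid[aln.reference_id]
                rec.reference_start = aln.start - 1
                rec.mapping_quality = 255
                rec.cigarstring = f"{len(seq)}M"
                rec.set_tag("NM", aln.mismatches)
                rec.set_tag("XC", len(aln.cochampions))
                out.write(rec)


def read_sam(path) -> tuple[dict[str, list[Alignment]], dict[str, str]]:
    """Read a SAM written by :func:`write_sam` back into alignments + reads."""
    alignments: dict[str, list[Alignment]] = {}
    reads: dict[str, str] = {}
    with pysam.AlignmentFile(str(path), "r") as handle:
        grouped: dict[str, list[pysam.AlignedSegment]] = {}
        for rec in handle:
            grouped.setdefault(rec.query_name, []).append(rec)
        for read_id, recs in grouped.items():
            cochampions = frozenset(r.reference_name for r in recs)
            reads[read_id] = recs[0].query_sequence
            alignments[read_id] = [
                Alignment(
                    read_id=read_id,
                    reference_id=r.reference_name,
                    start=r.reference_start + 1,
                    mismatches=r.get_tag("NM"),
                    ambiguous=len(cochampions) >= 2,
                    cochampions=cochampions,
                )
                for r in sorted(recs, key=lambda r: r.reference_name)
            ]
    return alignments, reads


# ---------------------------------------------------------------------------
# per-site tables

def site_table(calls: Sequence[SiteCall], structural_labels: Mapping[tuple[str, int], int] | None = None) -> pd.DataFrame:
    rows = []
    for call in calls:
        label = None
        if structural_labels is not None:
            label = structural_labels.get((call.reference_id, call.position))
        rows.append(
            {
                "reference_id": call.reference_id,
                "position": call.position,
                "structural_position": label,
                "n_C": round(call.n_C, 4),
                "n_T": round(call.n_T, 4),
                "coverage": round(call.coverage, 4),
                "methylation": None if call.methylation is None else round(call.methylation, 6),
                "status": call.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["reference_id", "position", "structural_position", "n_C", "n_T", "coverage", "methylation", "status"],
    )


def write_site_table(calls, path, structural_labels=None) -> None:
    site_table(calls, structural_labels).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_methylated_bed(calls: Sequence[SiteCall], path) -> None:
    """BED track of methylated sites (0-based half-open single-base intervals)."""
    with open(path, "w") as handle:
        for call in calls:
            if call.status == "methylated":
                handle.write(
                    f"{call.reference_id}\t{call.position - 1}\t{call.position}\t"
                    f"m5C\t{call.methylation:.4f}\t+\n"
                )


def heatmap_matrix(per_sample_calls: Mapping[str, Sequence[SiteCall]]) -> pd.DataFrame:
    """Sites x samples matrix of percent methylation; NA where no_call.

    Mirrors the published heatmap semantics in which cytosines covered by
    fewer than the minimum read count are blanked rather than shown as 0%.
    """
    frames = {}
    for sample, calls in per_sample_calls.items():
        values = {}
        for call in calls:
            key = f"{call.reference_id}:C{call.position}"
            if call.status == NO_CALL or call.methylation is None:
                values[key] = float("nan")
            else:
                values[key] = 100.0 * call.methylation
        frames[sample] = pd.Series(values)
    return pd.DataFrame(frames)
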
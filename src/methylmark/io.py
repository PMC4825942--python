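"""CSV/FASTA readers and writers for the pipeline's file interfaces."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bisulfite import BisulfiteRead, ReferenceSequence

__all__ = [
    "read_subjects",
    "read_qpcr",
    "read_qmsp",
    "read_array",
    "write_reference_fasta",
    "read_reference_fasta",
    "write_reads_fasta",
    "read_reads_fasta",
]

SUBJECT_COLUMNS = ["subject_id", "group", "age", "sex", "mmse", "apoe4", "methylation_pct"]
QPCR_COLUMNS = ["sample_id", "condition", "gene_role", "replicate", "ct"]
QMSP_COLUMNS = ["sample_id", "replicate", "ct_meth", "ct_unmeth", "ct_internal"]
ARRAY_COLUMNS = [
    "probe_id", "group", "replicate",
    "signal_meth", "signal_unmeth", "background", "detection_p",
]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_subjects(path) -> pd.DataFrame:
    return _read_csv(path, SUBJECT_COLUMNS)


def read_qpcr(path) -> pd.DataFrame:
    return _read_csv(path, QPCR_COLUMNS)


def read_qmsp(path) -> pd.DataFrame:
    return _read_csv(path, QMSP_COLUMNS)


def read_array(path) -> pd.DataFrame:
    return _read_csv(path, ARRAY_COLUMNS)


def write_reference_fasta(ref: ReferenceSequence, path) -> None:
    """Reference FASTA whose header carries the genomic anchoring.

    Header form: ``<chrom>:<start>-<end> tss=<coord> strand=+`` so the
    record round-trips through :func:`read_reference_fasta`.
    """
    rec = SeqRecord(
        Seq(ref.bases),
        id=f"{ref.chrom}:{ref.start}-{ref.end}",
        description=f"tss={ref.tss} strand={ref.strand}",
    )
    SeqIO.write([rec], str(path), "fasta")


def read_reference_fasta(path, tss: int | None = None) -> ReferenceSequence:
    """Parse a reference FASTA written by :func:`write_reference_fasta`.

    ``tss`` overrides (or supplies, for externally produced files) the TSS
    coordinate; the TSS is study metadata, not derivable from sequence.
    """
    rec = next(SeqIO.parse(str(path), "fasta"))
    chrom, _, interval = rec.id.partition(":")
    try:
        start_s, _, end_s = interval.partition("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(
            f"{path}: reference FASTA id must look like 'chrom:start-end', got {rec.id!r}"
        ) from exc
    if tss is None:
        for token in rec.description.split():
            if token.startswith("tss="):
                tss = int(token[4:])
        if tss is None:
            raise ValueError(f"{path}: no tss= token in header and no --tss given")
    return ReferenceSequence(chrom=chrom, start=start, end=end, tss=tss, bases=str(rec.seq).upper())


def write_reads_fasta(reads: list[BisulfiteRead], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.bases), id=r.read_id, description="") for r in reads],
        str(path),
        "fasta",
    )


def read_reads_fasta(path) -> list[BisulfiteRead]:
    return [
        BisulfiteRead(read_id=rec.id, bases=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
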
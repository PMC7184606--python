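"""Reading and writing the tabular dialects used throughout the pipeline.

Per-read poly(A) estimates travel as pandas DataFrames with the columns

    read_id, transcript_id, polya_length, qc_tag, sample_id

mirroring the Nanopolish ``polya`` output (``readname``/``contig`` headers on
disk).  Sample sheets, barcode tables and result tables are plain TSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PASS",
    "QC_FAIL_TAGS",
    "TailTableFormatError",
    "read_tail_table",
    "write_tail_table",
    "filter_qc_pass",
    "read_sample_sheet",
    "read_barcode_table",
    "write_barcode_table",
    "read_fasta",
    "write_fasta",
]

#: QC tag marking a reliable tail segmentation; only these reads enter analysis.
PASS = "PASS"

#: Failure codes emitted by the tail caller (closed set used by the simulator).
QC_FAIL_TAGS = ("SUFFCLIP", "ADAPTER", "READ_FAILED_LOAD", "NOREGION")

#: Canonical in-memory column order for per-read tail records.
TAIL_COLUMNS = ["read_id", "transcript_id", "polya_length", "qc_tag", "sample_id"]

# On-disk header names (Nanopolish dialect) -> in-memory names.
_DISK_TO_MEM = {
    "readname": "read_id",
    "contig": "transcript_id",
    "polya_length": "polya_length",
    "qc_tag": "qc_tag",
}


class TailTableFormatError(ValueError):
    """A tail table, sample sheet or barcode table violates its format contract."""


def read_tail_table(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read a per-read poly(A) tail table (Nanopolish ``polya`` dialect).

    Both the full 10-column layout and a minimal 4-column layout are accepted;
    columns are located by header name, extra columns are ignored.  Rows whose
    tail length does not parse to a finite non-negative number are dropped
    with a warning (negative printed lengths are treated as corrupt).

    Parameters
    ----------
    path:
        TSV file with a header naming at least ``readname``, ``contig``,
        ``polya_length`` and ``qc_tag``.
    sample_id:
        Sample of origin, attached to every returned record.

    Returns
    -------
    DataFrame with columns ``read_id, transcript_id, polya_length, qc_tag,
    sample_id``.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        warnings.warn(f"tail table {path} is empty; returning no records")
        return pd.DataFrame(columns=TAIL_COLUMNS)

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _DISK_TO_MEM if c not in df.columns]
    if missing:
        raise TailTableFormatError(
            f"tail table {path} is missing required column(s): {', '.join(missing)}"
        )
    df = df[list(_DISK_TO_MEM)].rename(columns=_DISK_TO_MEM)
    lengths = pd.to_numeric(df["polya_length"], errors="coerce")
    bad = ~(lengths.notna() & (lengths >= 0))
    if bad.any():
        warnings.warn(
            f"tail table {path}: dropped {int(bad.sum())} row(s) with "
            "unparsable or negative tail length"
        )
        df = df[~bad]
        lengths = lengths[~bad]
    df = df.assign(polya_length=lengths.astype(float), sample_id=sample_id)
    return df.reset_index(drop=True)[TAIL_COLUMNS]


def write_tail_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write tail records back to the on-disk dialect (one sample per file)."""
    out = records.rename(
        columns={"read_id": "readname", "transcript_id": "contig"}
    )[["readname", "contig", "polya_length", "qc_tag"]]
    out.to_csv(path, sep="\t", index=False)


def filter_qc_pass(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only records whose QC tag is PASS, preserving input order.

    Idempotent; never modifies its input.
    """
    return records[records["qc_tag"] == PASS].copy()


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet (columns ``sample_id, condition, replicate_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "condition", "replicate_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TailTableFormatError(
            f"sample sheet {path} is missing column(s): {', '.join(missing)}"
        )
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise TailTableFormatError(f"duplicate sample_id(s) in sample sheet: {dupes}")
    return df[required]


def read_barcode_table(path: str | Path) -> pd.DataFrame:
    """Read a spike-in barcode table (``barcode_id, sequence, true_tail_length``)."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode_id": str, "sequence": str})
    required = ["barcode_id", "sequence", "true_tail_length"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TailTableFormatError(
            f"barcode table {path} is missing column(s): {', '.join(missing)}"
        )
    df = df[required].copy()
    df["true_tail_length"] = pd.to_numeric(df["true_tail_length"])
    if df["sequence"].str.len().eq(0).any() or df["sequence"].isna().any():
        raise TailTableFormatError("barcode table contains an empty sequence")
    if df["sequence"].duplicated().any():
        raise TailTableFormatError("barcode sequences must be pairwise distinct")
    return df


def write_barcode_table(barcodes: pd.DataFrame, path: str | Path) -> None:
    barcodes[["barcode_id", "sequence", "true_tail_length"]].to_csv(
        path, sep="\t", index=False
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (uppercased DNA)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
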
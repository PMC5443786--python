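"""Readers and writers for the pipeline's external formats.

FASTA and FASTQ parsing is delegated to Bio.SeqIO; this module adds the
normalisation and validation the pipeline relies on (uppercasing, U→T,
quality/sequence length checks, metadata invariants) and the tab-separated
OTU-table and sample-metadata conventions used throughout.

Every reader logs the number of records it returns at INFO so that
filtering losses can be audited stage by stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("smdiv")

METADATA_COLUMNS = ("sample_id", "site", "stage", "replicate", "barcode")
STAGES = ("emergence", "senescence")

_DNA = set("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates its format invariants."""


@dataclass(frozen=True)
class SampleMetadata:
    """One sequencing sample: site x vegetation stage x biological replicate.

    ``barcode``, when present, is the 10-nt sample tag ligated during the
    second PCR round and used for demultiplexing.
    """

    sample_id: str
    site: str
    stage: str
    replicate: int
    barcode: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise FormatError(
                f"sample {self.sample_id!r}: stage {self.stage!r} not in {STAGES}"
            )
        if not 1 <= int(self.replicate) <= 3:
            raise FormatError(
                f"sample {self.sample_id!r}: replicate must be 1..3, got {self.replicate}"
            )
        if self.barcode is not None and (set(self.barcode) - _DNA):
            raise FormatError(
                f"sample {self.sample_id!r}: barcode {self.barcode!r} has non-ACGT characters"
            )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` pairs.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``; line
    wrapping is transparent. An empty file yields an empty list; content
    before the first header is a malformed-header error naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                )
            break
    records = [
        (rec.id, str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    logger.info("read_fasta: %d records from %s", len(records), path)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as unwrapped FASTA."""
    records = list(records)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")
    logger.info("write_fasta: %d records to %s", len(records), path)


def read_fastq(path: str | Path):
    """Read FASTQ (PHRED+33) into :class:`smdiv.seqprep.AmpliconRead` objects.

    Quality strings must match sequence length; Bio.SeqIO raises on
    truncated records and length mismatches, which we re-raise with the
    record context.
    """
    from .seqprep import AmpliconRead  # local import to avoid a cycle

    path = Path(path)
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            seq = str(rec.seq).upper()
            if len(quals) != len(seq):  # pragma: no cover - SeqIO enforces this
                raise FormatError(f"{path}: record {rec.id}: quality length mismatch")
            reads.append(AmpliconRead(id=rec.id, sequence=seq, qualities=list(quals)))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FASTQ: {exc}") from exc
    logger.info("read_fastq: %d reads from %s", len(reads), path)
    return reads


def write_fastq(reads, path: str | Path) -> None:
    """Write AmpliconReads with qualities as PHRED+33 FASTQ."""
    reads = list(reads)
    with open(path, "w") as fh:
        for read in reads:
            if read.qualities is None:
                raise FormatError(f"read {read.id}: cannot write FASTQ without qualities")
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
    logger.info("write_fastq: %d reads to %s", len(reads), path)


# ---------------------------------------------------------------------------
# OTU tables: TSV, rows = OTUs, columns = samples, "#OTU_ID" corner cell.
# ---------------------------------------------------------------------------

def write_otu_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an OTU x sample count table as TSV with a ``#OTU_ID`` corner."""
    out = table.copy()
    out.index.name = "#OTU_ID"
    out.to_csv(path, sep="\t")
    logger.info(
        "write_otu_table: %d OTUs x %d samples to %s", *table.shape, path
    )


def read_otu_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV OTU table; cells must be non-negative integers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    df.index = df.index.astype(str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate OTU or sample labels")
    for col in df.columns:
        vals = df[col]
        if not (vals == vals.astype(int)).all():
            raise FormatError(f"{path}: non-integer count in column {col!r}")
        if (vals < 0).any():
            bad = vals.index[vals < 0][0]
            raise FormatError(f"{path}: negative count at OTU {bad!r}, sample {col!r}")
    df = df.astype(int)
    logger.info("read_otu_table: %d OTUs x %d samples from %s", *df.shape, path)
    return df


# ---------------------------------------------------------------------------
# Sample metadata: TSV with fixed column names; extra columns are preserved
# in the returned frame but ignored by the pipeline.
# ---------------------------------------------------------------------------

def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a metadata frame against the sampling-design invariants."""
    missing = [c for c in METADATA_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    for _, row in df.iterrows():
        SampleMetadata(
            sample_id=str(row["sample_id"]),
            site=str(row["site"]),
            stage=str(row["stage"]),
            replicate=int(row["replicate"]),
            barcode=None if pd.isna(row.get("barcode")) else str(row["barcode"]),
        )
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r}")
    triples = df[["site", "stage", "replicate"]].apply(tuple, axis=1)
    if triples.duplicated().any():
        dup = triples[triples.duplicated()].iloc[0]
        raise FormatError(f"duplicate (site, stage, replicate) triple {dup}")
    if "barcode" in df.columns:
        codes = df["barcode"].dropna().astype(str)
        if codes.duplicated().any():
            raise FormatError(f"duplicate barcode {codes[codes.duplicated()].iloc[0]!r}")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "sample_id": str})
    df = validate_metadata(df)
    logger.info("read_metadata: %d samples from %s", len(df), path)
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(df)
    df.to_csv(path, sep="\t", index=False)
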
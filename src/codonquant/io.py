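"""Readers and writers for the plain-text interchange formats.

All tables are TSV with headers; FASTA is 60-column wrapped. Floats are
written with a fixed ``%.10g`` format so reruns are byte-identical.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .simulate import CodingSequence, SampleDesign

FLOAT_FORMAT = "%.10g"

PSM_FIXED_COLUMNS = ["psm_id", "peptide", "protein_ids", "start_aa",
                     "score", "is_decoy", "has_ms3"]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as 60-column wrapped FASTA."""
    seq_records = [SeqRecord(Seq(seq), id=rid, description="")
                   for rid, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValidationError(f"no FASTA records in {path}")
    return out


def write_cds_fasta(cds_list: Sequence[CodingSequence], path: str | Path) -> None:
    write_fasta(((c.id, c.nt_seq) for c in cds_list), path)


def write_protein_fasta(cds_list: Sequence[CodingSequence], path: str | Path) -> None:
    write_fasta(((c.id, c.aa_seq) for c in cds_list), path)


def read_cds_fasta(path: str | Path) -> dict[str, CodingSequence]:
    """Read and validate a CDS FASTA (in-frame, stop-free)."""
    return {rid: CodingSequence(rid, seq)
            for rid, seq in read_fasta(path).items()}


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sn_columns(df: pd.DataFrame) -> list[str]:
    """The reporter S:N columns of a PSM table, in channel order."""
    cols = [c for c in df.columns if re.fullmatch(r"sn_ch\d+", c)]
    return sorted(cols, key=lambda c: int(c[5:]))


def write_psm_table(psms: pd.DataFrame, path: str | Path) -> None:
    """Write the PSM TSV; missing reporter values become empty strings."""
    cols = PSM_FIXED_COLUMNS + sn_columns(psms)
    missing = [c for c in cols if c not in psms.columns]
    if missing:
        raise ValidationError(f"PSM table missing columns {missing}")
    write_table(psms[cols], path)


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read the PSM TSV; empty reporter cells become NaN (never zero)."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "protein_ids": str})
    missing = [c for c in PSM_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"PSM table {path} missing columns {missing}")
    if not sn_columns(df):
        raise ValidationError(f"PSM table {path} has no sn_chNN columns")
    return df


def write_design(design: SampleDesign, path: str | Path) -> None:
    write_table(design.to_frame(), path)


def read_design(path: str | Path) -> SampleDesign:
    return SampleDesign.from_frame(read_table(path))
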
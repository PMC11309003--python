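"""FASTA/TSV readers and writers used across the pipeline stages."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping.

    Record ids are taken verbatim up to the first whitespace (Biopython's
    convention, which matches the pipeline's id scheme).
    """
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(recs, str(path), "fasta")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
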
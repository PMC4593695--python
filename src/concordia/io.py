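"""Flat-file I/O: FASTA genomes and the annotation table.

All inter-stage artifacts are plain text (FASTA, TSV, JSON) so each pipeline
stage can be rerun from its on-disk inputs.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ANNOTATION_COLUMNS = ["transcript_id", "chromosome", "start", "end", "strand"]


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    """Write a chromosome-name -> sequence map as FASTA (60-column wrap)."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a chromosome-name -> sequence map."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    return df
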
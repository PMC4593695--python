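"""Probe records for the two platforms, with TSV round-tripping.

An :class:`ArrayProbe` is a physical ~70-mer spotted on the microarray; it
knows its sequence, the chromosome it was designed against, and a (possibly
empty) set of transcript IDs. An :class:`ExpressionProbe` is a virtual
quantification interval spanning one annotated mRNA transcript, over which
RNA-seq reads are counted; it carries exactly one transcript ID.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

_VALID_BASES = set("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ArrayProbe:
    """A microarray probe: id, sequence, design chromosome, transcript IDs."""

    probe_id: str
    sequence: str
    chromosome: str
    ensembl_ids: frozenset[str] = field(default_factory=frozenset)
    decoy: bool = False

    def __post_init__(self):
        if not self.sequence or set(self.sequence) - _VALID_BASES:
            raise ValueError(
                f"probe {self.probe_id}: sequence must be non-empty over A/C/G/T"
            )


@dataclass(frozen=True)
class ExpressionProbe:
    """An RNA-seq feature probe spanning one annotated transcript.

    Coordinates are 1-based inclusive; ``sequence`` is the forward-strand
    reference slice between them.
    """

    probe_id: str
    chromosome: str
    start: int
    end: int
    ensembl_id: str
    sequence: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"probe {self.probe_id}: start > end")
        if len(self.sequence) != self.length:
            raise ValueError(
                f"probe {self.probe_id}: sequence length {len(self.sequence)} "
                f"does not match span {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------- TSV I/O

def array_probes_to_frame(probes: Iterable[ArrayProbe]) -> pd.DataFrame:
    rows = [
        {
            "probe_id": p.probe_id,
            "sequence": p.sequence,
            "chromosome": p.chromosome,
            "ensembl_ids": ";".join(sorted(p.ensembl_ids)),
            "decoy": int(p.decoy),
        }
        for p in probes
    ]
    return pd.DataFrame(rows, columns=["probe_id", "sequence", "chromosome", "ensembl_ids", "decoy"])


def array_probes_from_frame(df: pd.DataFrame) -> list[ArrayProbe]:
    out = []
    for row in df.itertuples(index=False):
        ids = frozenset(x for x in str(row.ensembl_ids).split(";") if x and x != "nan")
        out.append(
            ArrayProbe(
                probe_id=str(row.probe_id),
                sequence=str(row.sequence),
                chromosome=str(row.chromosome),
                ensembl_ids=ids,
                decoy=bool(int(row.decoy)),
            )
        )
    return out


def write_array_probes(probes: Iterable[ArrayProbe], path: str | Path) -> None:
    array_probes_to_frame(probes).to_csv(path, sep="\t", index=False)


def read_array_probes(path: str | Path) -> list[ArrayProbe]:
    return array_probes_from_frame(pd.read_csv(path, sep="\t", keep_default_na=False))


def expression_probes_to_frame(probes: Iterable[ExpressionProbe]) -> pd.DataFrame:
    rows = [
        {
            "probe_id": p.probe_id,
            "chromosome": p.chromosome,
            "start": p.start,
            "end": p.end,
            "ensembl_id": p.ensembl_id,
        }
        for p in probes
    ]
    return pd.DataFrame(rows, columns=["probe_id", "chromosome", "start", "end", "ensembl_id"])


def write_expression_probes(probes: Iterable[ExpressionProbe], path: str | Path) -> None:
    expression_probes_to_frame(probes).to_csv(path, sep="\t", index=False)


def read_expression_probes(path: str | Path, genome: Mapping[str, str]) -> list[ExpressionProbe]:
    """Read probes from TSV, re-extracting sequences from ``genome``."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        chrom = str(row.chromosome)
        seq = genome[chrom][int(row.start) - 1 : int(row.end)]
        out.append(
            ExpressionProbe(
                probe_id=str(row.probe_id),
                chromosome=chrom,
                start=int(row.start),
                end=int(row.end),
                ensembl_id=str(row.ensembl_id),
                sequence=seq,
            )
        )
    return out
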
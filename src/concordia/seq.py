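"""RNA-seq side of the pipeline: feature probes, RPKM, pooling, fold changes.

Quantification starts from per-probe read counts (one feature probe per
annotated mRNA transcript). Counts are normalized as RPKM
(``1e9 * count / (probe_length * total_reads)``), replicates are pooled by
summing raw reads and renormalizing, and fold changes are taken on RPKM
values after adding a small pseudocount to both numerator and denominator.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .foldchange import FoldChangeTable
from .probes import ExpressionProbe

DEFAULT_PSEUDOCOUNT = 0.05


def feature_probes_from_annotation(
    annotations: pd.DataFrame, genome: Mapping[str, str]
) -> list[ExpressionProbe]:
    """One feature probe per annotated transcript, spanning its full extent.

    Sequences are extracted from the forward strand of the reference;
    coordinates are 1-based inclusive. Out-of-bounds annotations are rejected
    with the offending record named.
    """
    probes = []
    for row in annotations.itertuples(index=False):
        chrom = str(row.chromosome)
        if chrom not in genome:
            raise ValueError(f"annotation {row.transcript_id}: unknown chromosome {chrom}")
        start, end = int(row.start), int(row.end)
        if start < 1 or end > len(genome[chrom]) or start > end:
            raise ValueError(
                f"annotation {row.transcript_id}: span {chrom}:{start}-{end} "
                f"outside chromosome bounds (1-{len(genome[chrom])})"
            )
        probes.append(
            ExpressionProbe(
                probe_id=f"RP_{row.transcript_id}",
                chromosome=chrom,
                start=start,
                end=end,
                ensembl_id=str(row.transcript_id),
                sequence=genome[chrom][start - 1 : end],
            )
        )
    return probes


@dataclass
class CountTable:
    """Per-probe RNA-seq read counts for one sample (or a pooled pair).

    ``data`` is indexed by probe_id with columns ``raw_count`` (int) and
    ``length`` (probe length, bp); ``total_reads`` is the sum of raw counts
    assigned in the sample. ``rpkm`` is present after normalization.
    """

    sample: str
    data: pd.DataFrame
    total_reads: int = 0

    def __post_init__(self):
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        if self.data.index.has_duplicates:
            raise ValueError(f"{self.sample}: duplicate probe ids")
        if (self.data["raw_count"] < 0).any():
            raise ValueError(f"{self.sample}: negative raw counts")
        if self.total_reads == 0:
            self.total_reads = int(self.data["raw_count"].sum())

    @property
    def rpkm(self) -> pd.Series:
        if "rpkm" not in self.data.columns:
            raise ValueError(f"{self.sample}: not RPKM-normalized yet")
        return self.data["rpkm"]

    def to_tsv(self, path: str | Path) -> None:
        self.data.rename_axis("probe_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, sample: str | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        return cls(sample or str(path), df)


def count_table_from_probes(
    sample: str, probes: Sequence[ExpressionProbe], counts: np.ndarray
) -> CountTable:
    df = pd.DataFrame(
        {
            "raw_count": np.asarray(counts, dtype=np.int64),
            "length": [p.length for p in probes],
        },
        index=pd.Index([p.probe_id for p in probes], name="probe_id"),
    )
    return CountTable(sample, df)


def rpkm_normalize(table: CountTable) -> CountTable:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm = 1e9 * raw_count / (length * total_reads); raw counts are kept
    alongside. Rejects tables with zero assigned reads.
    """
    if table.total_reads <= 0:
        raise ValueError(f"{table.sample}: cannot RPKM-normalize with zero total reads")
    out = table.data.copy()
    out["rpkm"] = 1e9 * out["raw_count"] / (out["length"] * table.total_reads)
    return CountTable(table.sample, out, total_reads=table.total_reads)


def pool_replicates(a: CountTable, b: CountTable, sample: str | None = None) -> CountTable:
    """Combine two replicates of the same state by summing raw reads.

    Totals are summed and RPKM is recomputed on the pooled totals, which is
    read-level pooling rather than an average of per-replicate RPKMs.
    """
    if set(a.data.index) != set(b.data.index):
        raise ValueError(f"cannot pool {a.sample} and {b.sample}: probe sets differ")
    bb = b.data.reindex(a.data.index)
    if (a.data["length"] != bb["length"]).any():
        raise ValueError(f"cannot pool {a.sample} and {b.sample}: probe lengths differ")
    pooled = pd.DataFrame(
        {
            "raw_count": a.data["raw_count"] + bb["raw_count"],
            "length": a.data["length"],
        },
        index=a.data.index,
    )
    out = CountTable(sample or f"{a.sample}+{b.sample}", pooled,
                     total_reads=a.total_reads + b.total_reads)
    return rpkm_normalize(out)


def seq_fold_changes(
    pro: CountTable,
    qui: CountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    source: str | None = None,
) -> FoldChangeTable:
    """Per-probe fold change (QUI/PRO) on RPKM values.

    A fixed pseudocount (default 0.05) is added to both the numerator and
    denominator to prevent division by zero; with a zero pseudocount any
    unexpressed PRO probe would make the ratio undefined, so that is rejected.
    """
    if set(pro.data.index) != set(qui.data.index):
        raise ValueError("fold change requires identical probe sets in both states")
    rp = pro.rpkm
    rq = qui.rpkm.reindex(rp.index)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and ((rp == 0).any() or (rq == 0).any()):
        raise ValueError("pseudocount must be > 0 when any RPKM is zero")
    fc = (rq + pseudocount) / (rp + pseudocount)
    return FoldChangeTable(source or f"{qui.sample}/{pro.sample}", fc)
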
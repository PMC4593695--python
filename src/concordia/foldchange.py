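"""Per-probe fold-change tables (quiescent over proliferative)."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class FoldChangeTable:
    """Per-probe QUI/PRO fold changes from one platform or source.

    ``fc`` is a pandas Series indexed by probe_id; all values must be
    strictly positive so the base-2 logarithm is always defined.
    """

    source: str
    fc: pd.Series

    def __post_init__(self):
        self.fc = pd.Series(self.fc, dtype=float)
        self.fc.index = self.fc.index.astype(str)
        if self.fc.index.has_duplicates:
            raise ValueError(f"{self.source}: duplicate probe ids in fold-change table")
        if (self.fc <= 0).any() or not np.isfinite(self.fc).all():
            bad = int(((self.fc <= 0) | ~np.isfinite(self.fc)).sum())
            raise ValueError(f"{self.source}: {bad} non-positive/non-finite fold changes")

    @property
    def log2_fc(self) -> pd.Series:
        return np.log2(self.fc)

    def __len__(self) -> int:
        return len(self.fc)

    def reciprocal(self, source: str | None = None) -> "FoldChangeTable":
        return FoldChangeTable(source or f"{self.source}(1/fc)", 1.0 / self.fc)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"fc": self.fc, "log2_fc": self.log2_fc})
        df.rename_axis("probe_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, source: str | None = None) -> "FoldChangeTable":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        return cls(source or str(path), df["fc"])
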
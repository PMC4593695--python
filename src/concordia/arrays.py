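"""Two-channel microarray processing.

A scan carries raw Cy3/Cy5 intensities per probe plus a dye orientation
saying which channel holds the quiescent sample. Processing follows the
classical two-colour workflow: invert cross-channel (fluorophore crosstalk)
bleed-through with a symmetric linear unmixing model, remove
intensity-dependent dye bias by LOWESS on the MA representation, then form
per-probe QUI/PRO fold changes. Replicate arrays are combined by the
geometric mean of their fold changes. Dye swaps are encoded as orientation
metadata, never by relabelling the raw intensity columns.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .foldchange import FoldChangeTable

QUI_ON_CY5 = "qui-cy5"
QUI_ON_CY3 = "qui-cy3"
ORIENTATIONS = (QUI_ON_CY5, QUI_ON_CY3)

#: floor applied to intensities driven negative by crosstalk unmixing
UNMIX_EPSILON = 1e-6

DEFAULT_LOWESS_SPAN = 0.3
LOWESS_ROBUSTIFYING_ITERATIONS = 3
MIN_PROBES_FOR_LOWESS = 10


@dataclass
class ArrayScan:
    """One two-channel scan: per-probe (cy3, cy5) intensities + orientation.

    ``data`` is indexed by probe_id with float columns ``cy3``/``cy5`` and a
    boolean ``excluded`` flag (spots without sufficient signal, provided as
    input metadata). Excluded probes are carried along but never contribute
    to normalization or fold changes.
    """

    array_id: str
    orientation: str
    data: pd.DataFrame

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"{self.array_id}: orientation must be one of {ORIENTATIONS}"
            )
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        if self.data.index.has_duplicates:
            raise ValueError(f"{self.array_id}: duplicate probe ids")
        if "excluded" not in self.data.columns:
            self.data["excluded"] = False
        if (self.data.loc[~self.data["excluded"], ["cy3", "cy5"]] < 0).any().any():
            raise ValueError(f"{self.array_id}: negative intensities")

    @property
    def retained(self) -> pd.DataFrame:
        return self.data.loc[~self.data["excluded"]]

    @property
    def qui_channel(self) -> str:
        return "cy5" if self.orientation == QUI_ON_CY5 else "cy3"

    @property
    def pro_channel(self) -> str:
        return "cy3" if self.orientation == QUI_ON_CY5 else "cy5"

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["excluded"] = out["excluded"].astype(int)
        out.rename_axis("probe_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, array_id: str, orientation: str) -> "ArrayScan":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        df["excluded"] = df["excluded"].astype(bool)
        return cls(array_id, orientation, df)


def cross_channel_correct(scan: ArrayScan, alpha: float) -> ArrayScan:
    """Invert symmetric crosstalk mixing observed_A = clean_A + alpha*clean_B.

    The exact algebraic inverse is ``clean_A = (obs_A - alpha*obs_B)/(1 - alpha^2)``
    (and symmetrically for B). Results driven negative by noise are floored
    at a small positive epsilon and flagged in a ``floored`` column.
    ``alpha >= 0.5`` is rejected: near the singular mixing regime the
    unmixing amplifies noise without bound, so it is disallowed by policy.
    """
    if not 0.0 <= alpha < 0.5:
        raise ValueError(f"crosstalk alpha must be in [0, 0.5), got {alpha}")
    out = scan.data.copy()
    denom = 1.0 - alpha * alpha
    cy3 = (scan.data["cy3"] - alpha * scan.data["cy5"]) / denom
    cy5 = (scan.data["cy5"] - alpha * scan.data["cy3"]) / denom
    floored = (cy3 < 0) | (cy5 < 0)
    out["cy3"] = cy3.clip(lower=UNMIX_EPSILON)
    out["cy5"] = cy5.clip(lower=UNMIX_EPSILON)
    out["floored"] = floored
    return ArrayScan(scan.array_id, scan.orientation, out)


def lowess_normalize(scan: ArrayScan, span: float = DEFAULT_LOWESS_SPAN) -> ArrayScan:
    """Within-array MA-LOWESS normalization.

    With M = log2(cy5/cy3) and A = (log2 cy5 + log2 cy3)/2, a LOWESS curve
    M̂(A) (tricube weights, ``span`` fraction of the data, 3 robustifying
    iterations) is subtracted from M, and channels are reconstructed so A is
    preserved exactly: cy5 = 2^(A + M'/2), cy3 = 2^(A - M'/2).
    """
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must be in (0, 1], got {span}")
    ret = scan.retained
    if len(ret) < MIN_PROBES_FOR_LOWESS:
        raise ValueError(
            f"{scan.array_id}: LOWESS needs >= {MIN_PROBES_FOR_LOWESS} retained probes, "
            f"got {len(ret)}"
        )
    if (ret[["cy3", "cy5"]] <= 0).any().any():
        raise ValueError(f"{scan.array_id}: LOWESS requires positive intensities")
    l3 = np.log2(ret["cy3"].to_numpy())
    l5 = np.log2(ret["cy5"].to_numpy())
    m = l5 - l3
    a = 0.5 * (l5 + l3)
    fitted = _sm_lowess(
        m, a, frac=span, it=LOWESS_ROBUSTIFYING_ITERATIONS, return_sorted=False
    )
    m_new = m - fitted
    out = scan.data.copy()
    out.loc[ret.index, "cy5"] = np.exp2(a + 0.5 * m_new)
    out.loc[ret.index, "cy3"] = np.exp2(a - 0.5 * m_new)
    return ArrayScan(scan.array_id, scan.orientation, out)


def swap_orientation(scan: ArrayScan) -> ArrayScan:
    """Artificially swap the dyes: flip orientation metadata, leave intensities alone.

    Applying it twice restores the original fold-change table (involution);
    downstream fold changes become per-probe reciprocals.
    """
    flipped = QUI_ON_CY3 if scan.orientation == QUI_ON_CY5 else QUI_ON_CY5
    return ArrayScan(scan.array_id, flipped, scan.data)


def array_fold_changes(scan: ArrayScan, source: str | None = None) -> FoldChangeTable:
    """Per-probe QUI/PRO fold change for one scan under its dye orientation.

    Excluded probes and probes with a zero PRO-channel intensity are left out
    of the table (the latter are reported via the returned table's source
    metadata being unaffected; they are simply dropped).
    """
    ret = scan.retained
    qui = ret[scan.qui_channel]
    pro = ret[scan.pro_channel]
    ok = (pro > 0) & (qui > 0)
    fc = (qui[ok] / pro[ok]).astype(float)
    return FoldChangeTable(source or scan.array_id, fc)


def combine_arrays_geometric_mean(
    tables: Sequence[FoldChangeTable], source: str = "all"
) -> FoldChangeTable:
    """Geometric mean of fold changes across arrays, over their common probes.

    Equivalent to the arithmetic mean of log2 fold changes. Commutes with
    taking per-array reciprocals (dye-swap coherence).
    """
    if len(tables) == 0:
        raise ValueError("need at least one fold-change table")
    common = tables[0].fc.index
    for t in tables[1:]:
        common = common.intersection(t.fc.index)
    common = common.sort_values()
    if len(common) == 0:
        raise ValueError("no probes shared by all fold-change tables")
    log_mean = np.mean([t.log2_fc.reindex(common) for t in tables], axis=0)
    return FoldChangeTable(source, pd.Series(np.exp2(log_mean), index=common))
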
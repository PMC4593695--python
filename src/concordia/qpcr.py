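"""qRT-PCR arbitration: ddCT fold changes and platform adjudication.

Relative quantification follows the classical 2^-ddCT method with multiple
normalizer genes: for each target/normalizer pair,
ddCT = (CT_target,QUI - CT_norm,QUI) - (CT_target,PRO - CT_norm,PRO) and
FC = 2^-ddCT, assuming 100 % amplification efficiency. Per-gene fold changes
from the four normalizers are averaged (arithmetic mean of the FCs by
default; geometric available). Platform agreement is adjudicated per gene by
which platform's log2 FC lies closer to the qPCR log2 FC.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import CorrelationTriple, correlation_suite

#: log-distance differences below this are declared ties
TIE_TOLERANCE = 1e-12


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate-averaged CT values for one gene in both states."""

    gene: str
    ct_pro: float
    ct_qui: float

    def __post_init__(self):
        for v in (self.ct_pro, self.ct_qui):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{self.gene}: CT values must be finite and > 0")


def measurements_from_ct_table(ct: pd.DataFrame) -> dict[str, QpcrMeasurement]:
    """Average replicate CTs per gene and state.

    Expects columns gene, state (PRO/QUI), replicate, ct. Averaging happens
    at the CT stage, before any fold-change computation.
    """
    needed = {"gene", "state", "ct"}
    if not needed <= set(ct.columns):
        raise ValueError(f"CT table needs columns {sorted(needed)}")
    mean_ct = ct.groupby(["gene", "state"])["ct"].mean().unstack("state")
    if not {"PRO", "QUI"} <= set(mean_ct.columns):
        raise ValueError("CT table must contain both PRO and QUI states")
    return {
        g: QpcrMeasurement(g, float(row["PRO"]), float(row["QUI"]))
        for g, row in mean_ct.iterrows()
    }


def ddct_fold_change(target: QpcrMeasurement, normalizer: QpcrMeasurement) -> float:
    """2^-ddCT fold change of the target relative to one normalizer."""
    ddct = (target.ct_qui - normalizer.ct_qui) - (target.ct_pro - normalizer.ct_pro)
    return float(2.0 ** (-ddct))


def average_over_normalizers(fcs: Sequence[float], geometric: bool = False) -> float:
    """Combine per-normalizer fold changes (arithmetic mean by default)."""
    fcs = np.asarray(fcs, dtype=float)
    if fcs.size == 0:
        raise ValueError("need at least one fold change")
    if (fcs <= 0).any():
        raise ValueError("fold changes must be > 0")
    if geometric:
        return float(np.exp2(np.mean(np.log2(fcs))))
    return float(np.mean(fcs))


def gene_level_array_fc(probe_fcs_for_gene: Sequence[float]) -> float:
    """Geometric mean of the array-probe fold changes mapping to one gene."""
    fcs = np.asarray(probe_fcs_for_gene, dtype=float)
    if fcs.size == 0:
        raise ValueError("need at least one probe fold change")
    if (fcs <= 0).any():
        raise ValueError("fold changes must be > 0")
    return float(np.exp2(np.mean(np.log2(fcs))))


def qpcr_fold_changes(
    ct: pd.DataFrame,
    normalizer_genes: Sequence[str],
    geometric: bool = False,
) -> pd.Series:
    """Per-gene qPCR fold change, averaged over the normalizer panel."""
    meas = measurements_from_ct_table(ct)
    missing = [g for g in normalizer_genes if g not in meas]
    if missing:
        raise ValueError(f"normalizer genes absent from CT table: {missing}")
    norms = [meas[g] for g in normalizer_genes]
    out = {}
    for g, m in meas.items():
        if g in set(normalizer_genes):
            continue
        out[g] = average_over_normalizers(
            [ddct_fold_change(m, n) for n in norms], geometric=geometric
        )
    return pd.Series(out, name="fc_qpcr").sort_index()


@dataclass(frozen=True)
class PlatformAgreement:
    """Correlation of each platform with qPCR, plus per-gene closer counts."""

    qpcr_vs_rnaseq: CorrelationTriple
    qpcr_vs_array: CorrelationTriple
    n_rnaseq_closer: int
    n_array_closer: int
    n_ties: int
    n_genes: int


def platform_agreement(
    genes: pd.DataFrame, min_qpcr_fc: float | None = None
) -> PlatformAgreement:
    """Adjudicate RNA-seq vs microarray against the qPCR reference.

    ``genes`` is indexed by gene with positive columns fc_qpcr, fc_rnaseq,
    fc_array. Each platform's fold changes are correlated with qPCR's, and
    per gene the platform whose log2 FC is closer to the qPCR log2 FC is
    counted (ties within 1e-12 in log distance). ``min_qpcr_fc`` optionally
    restricts to strongly changed genes (|FC| beyond the threshold in either
    direction, i.e. fc > t or fc < 1/t).
    """
    needed = {"fc_qpcr", "fc_rnaseq", "fc_array"}
    if not needed <= set(genes.columns):
        raise ValueError(f"need columns {sorted(needed)}")
    df = genes.copy()
    if min_qpcr_fc is not None:
        if min_qpcr_fc <= 0:
            raise ValueError("min_qpcr_fc must be > 0")
        df = df[(df["fc_qpcr"] > min_qpcr_fc) | (df["fc_qpcr"] < 1.0 / min_qpcr_fc)]
    if len(df) < 3:
        raise ValueError("need at least 3 genes after filtering")
    c_seq = correlation_suite(df["fc_qpcr"].to_numpy(), df["fc_rnaseq"].to_numpy())
    c_arr = correlation_suite(df["fc_qpcr"].to_numpy(), df["fc_array"].to_numpy())
    d_seq = np.abs(np.log2(df["fc_rnaseq"]) - np.log2(df["fc_qpcr"]))
    d_arr = np.abs(np.log2(df["fc_array"]) - np.log2(df["fc_qpcr"]))
    diff = d_seq - d_arr
    ties = np.abs(diff) < TIE_TOLERANCE
    return PlatformAgreement(
        qpcr_vs_rnaseq=c_seq,
        qpcr_vs_array=c_arr,
        n_rnaseq_closer=int(((diff < 0) & ~ties).sum()),
        n_array_closer=int(((diff > 0) & ~ties).sum()),
        n_ties=int(ties.sum()),
        n_genes=len(df),
    )
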
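"""Concordance statistics.

The workhorse is a three-correlation suite (Pearson on raw values, Pearson
on log2-transformed values, Spearman), applied to intensities, read counts
and fold changes. Two correlations from independent samples are compared via
Fisher's z-transformation. Agreement between the platforms' most-changed
probes is quantified by the size of the intersection of their top-k
fold-change lists, with an empirical permutation null (two independent
uniform k-subsets of the common probe universe per trial) and an exact
hypergeometric oracle for cross-checking. A simple threshold concordance
(how many probes above a fold-change cutoff on one platform are also above
it on the other) rounds out the suite.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .foldchange import FoldChangeTable

DEFAULT_N_TRIALS = 10_000


@dataclass(frozen=True)
class CorrelationTriple:
    """Pearson (raw), Pearson (log2) and Spearman coefficients on n pairs."""

    pearson: float
    pearson_log2: float
    spearman: float
    n: int


def correlation_suite(x: Sequence[float], y: Sequence[float]) -> CorrelationTriple:
    """The three correlation measures on strictly positive paired vectors.

    Log transformation is base 2 and applied only for the middle coefficient;
    Spearman uses average ranks for ties (and is unchanged by any monotone
    transform, so a single rank correlation covers both scales).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    n_bad = int((x <= 0).sum() + (y <= 0).sum())
    if n_bad:
        raise ValueError(f"{n_bad} non-positive values; log2 transform undefined")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors; correlation undefined")
    pearson = float(sps.pearsonr(x, y).statistic)
    pearson_log2 = float(sps.pearsonr(np.log2(x), np.log2(y)).statistic)
    spearman = float(sps.spearmanr(x, y).statistic)
    return CorrelationTriple(pearson, pearson_log2, spearman, len(x))


def compare_correlations_fisher_z(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Compare two independent correlations via Fisher's z-transformation.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); the p-value is
    two-sided from the standard normal.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1 for Fisher's z-transformation")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("need n > 3 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def top_k_list(fc_table: FoldChangeTable, k: int, direction: str = "highest") -> list[str]:
    """The k probe ids with the highest (or lowest) fold changes.

    Ties are broken by ascending probe id, so the list is deterministic.
    """
    if direction not in ("highest", "lowest"):
        raise ValueError("direction must be 'highest' or 'lowest'")
    if not 0 < k <= len(fc_table):
        raise ValueError(f"k={k} out of range for table of {len(fc_table)} probes")
    df = fc_table.fc.rename("fc").rename_axis("probe_id").reset_index()
    df = df.sort_values(
        ["fc", "probe_id"], ascending=[direction == "lowest", True], kind="mergesort"
    )
    return df["probe_id"].head(k).tolist()


@dataclass(frozen=True)
class OverlapTestResult:
    """Observed top-k overlap with its permutation-null p-value."""

    k: int
    n_observed: int
    n_trials: int
    n_trials_geq: int
    p_value: float
    seed: int
    universe_size: int


def overlap_null_distribution(
    k: int, universe_size: int, n_trials: int, seed: int
) -> np.ndarray:
    """Null overlaps: per trial, |A ∩ B| for two independent uniform k-subsets.

    Each trial draws k probes without replacement, replaces them, and draws k
    again; the returned array holds the n_trials intersection sizes.
    """
    if not 0 < k <= universe_size:
        raise ValueError("need 0 < k <= universe_size")
    rng = np.random.default_rng(seed)
    if n_trials * universe_size <= 50_000_000:
        # vectorized: argpartition of iid uniforms yields a uniform k-subset per row
        def draw_masks() -> np.ndarray:
            idx = np.argpartition(
                rng.random((n_trials, universe_size)), k - 1, axis=1
            )[:, :k]
            mask = np.zeros((n_trials, universe_size), dtype=bool)
            mask[np.arange(n_trials)[:, None], idx] = True
            return mask

        return (draw_masks() & draw_masks()).sum(axis=1).astype(np.int64)
    out = np.empty(n_trials, dtype=np.int64)
    for t in range(n_trials):
        a = rng.choice(universe_size, size=k, replace=False)
        b = rng.choice(universe_size, size=k, replace=False)
        out[t] = np.intersect1d(a, b, assume_unique=True).size
    return out


def overlap_permutation_test(
    list_a: Sequence[str],
    list_b: Sequence[str],
    universe_size: int,
    n_trials: int = DEFAULT_N_TRIALS,
    seed: int = 0,
    null: np.ndarray | None = None,
) -> OverlapTestResult:
    """Empirical test of top-k list overlap against random k-subsets.

    The p-value is the proportion of trials whose overlap was equal to or
    greater than the observed one (the raw trial count is reported too).
    A precomputed null distribution for the same (k, universe_size) may be
    supplied to amortize simulation across many list pairs.
    """
    if len(set(list_a)) != len(list_a) or len(set(list_b)) != len(list_b):
        raise ValueError("duplicate ids within a list")
    if len(list_a) != len(list_b):
        raise ValueError("lists must have equal size k")
    k = len(list_a)
    if k > universe_size:
        raise ValueError("k exceeds the universe size")
    n_observed = len(set(list_a) & set(list_b))
    if null is None:
        null = overlap_null_distribution(k, universe_size, n_trials, seed)
    elif len(null) != n_trials:
        n_trials = len(null)
    n_geq = int((null >= n_observed).sum())
    return OverlapTestResult(
        k=k,
        n_observed=n_observed,
        n_trials=n_trials,
        n_trials_geq=n_geq,
        p_value=n_geq / n_trials,
        seed=seed,
        universe_size=universe_size,
    )


def overlap_exact_pvalue(k: int, n_observed: int, universe_size: int) -> float:
    """Closed-form P(X >= n_observed), X ~ Hypergeometric(N, k, k).

    Conditioning on the first k-subset, the overlap with an independent
    second k-subset is hypergeometric; this is the exact counterpart of the
    permutation null, used as an oracle.
    """
    if not 0 < k <= universe_size:
        raise ValueError("need 0 < k <= universe_size")
    if not 0 <= n_observed <= k:
        raise ValueError("need 0 <= n_observed <= k")
    return float(sps.hypergeom.sf(n_observed - 1, universe_size, k, k))


@dataclass(frozen=True)
class ThresholdConcordance:
    threshold: float
    n_a_above: int
    n_both_above: int
    percent: float  # NaN when n_a_above == 0


def threshold_concordance(
    fc_a: FoldChangeTable, fc_b: FoldChangeTable, threshold: float
) -> ThresholdConcordance:
    """Among common probes with fc_a > threshold, the share with fc_b > threshold.

    The percentage is reported to one decimal; with no probe above threshold
    on side A it is undefined and reported as NaN.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    common = fc_a.fc.index.intersection(fc_b.fc.index)
    if len(common) == 0:
        raise ValueError("fold-change tables share no probes")
    a = fc_a.fc.reindex(common)
    b = fc_b.fc.reindex(common)
    above_a = a > threshold
    n_a = int(above_a.sum())
    n_both = int((above_a & (b > threshold)).sum())
    percent = round(100.0 * n_both / n_a, 1) if n_a else float("nan")
    return ThresholdConcordance(threshold, n_a, n_both, percent)


def pairwise_correlations(
    vectors: Mapping[str, pd.Series],
) -> dict[tuple[str, str], CorrelationTriple]:
    """Correlation triples for every unordered pair of labelled vectors.

    Vectors are aligned on their common index before each comparison; at
    least two sources sharing >= 3 probes are required.
    """
    labels = list(vectors)
    if len(labels) < 2:
        raise ValueError("need at least two sources")
    out = {}
    for a, b in combinations(labels, 2):
        common = vectors[a].index.intersection(vectors[b].index)
        if len(common) < 3:
            raise ValueError(f"sources {a} and {b} share fewer than 3 probes")
        out[(a, b)] = correlation_suite(
            vectors[a].reindex(common).to_numpy(), vectors[b].reindex(common).to_numpy()
        )
    return out


def reproducibility_report(
    fold_changes: Mapping[str, FoldChangeTable],
) -> pd.DataFrame:
    """Pairwise fold-change correlation grid across replicate sources.

    Returns a long-form table (source_a, source_b, pearson, pearson_log2,
    spearman, n), one row per unordered pair — the analogue of a replicate
    reproducibility matrix. Four sources yield the classic 6 pairs.
    """
    triples = pairwise_correlations({k: t.fc for k, t in fold_changes.items()})
    rows = [
        {"source_a": a, "source_b": b, "pearson": c.pearson,
         "pearson_log2": c.pearson_log2, "spearman": c.spearman, "n": c.n}
        for (a, b), c in triples.items()
    ]
    return pd.DataFrame(rows)
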
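"""Synthetic study generator.

Emulates a two-state (proliferative "PRO" vs quiescent "QUI") fibroblast
expression study measured on three platforms:

* a toy genome (a few chromosomes of random A/C/G/T sequence) with one
  annotated mRNA transcript per gene,
* ~70-mer two-channel microarray probes that are substrings of transcripts
  (forward or reverse-complement), plus two kinds of awkward probes —
  *decoys* whose sequence occurs nowhere in the genome and which carry no
  transcript ID, and *ID-fallback* probes whose sequence is scrambled but
  which keep their source transcript's ID,
* two-channel intensities with dye bias, cross-channel crosstalk and
  multiplicative log-normal noise under a configurable dye orientation,
* negative-binomial per-probe RNA-seq read counts, and
* qRT-PCR cycle-threshold (CT) values under a linear CT model.

Everything is a pure function of the :class:`~concordia.config.SimulationConfig`
(each simulator draws from its own named stream derived from the master
seed), so a fixed config reproduces byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arrays import ORIENTATIONS, ArrayScan
from .config import ConfigError, SimulationConfig
from .probes import ArrayProbe, ExpressionProbe, reverse_complement
from .seq import CountTable, count_table_from_probes, feature_probes_from_annotation

_BASES = np.array(list("ACGT"))

# fixed stream tags so each simulator has its own independent substream
_STREAM_GENOME = 1
_STREAM_EXPRESSION = 2
_STREAM_ARRAY = 3
_STREAM_RNASEQ = 4
_STREAM_QPCR = 5


def _rng(config_seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stream, *extra])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass
class GroundTruth:
    """Latent per-transcript abundances in both states and the true log2 FC.

    ``table`` is indexed by transcript_id with columns ``abundance_pro``,
    ``abundance_qui`` (positive, arbitrary expression units) and
    ``true_log2_fc`` (= log2(qui/pro)).
    """

    table: pd.DataFrame

    @property
    def transcript_ids(self) -> pd.Index:
        return self.table.index

    def abundance(self, state: str) -> pd.Series:
        if state not in ("PRO", "QUI"):
            raise ValueError(f"state must be PRO or QUI, got {state!r}")
        return self.table["abundance_pro" if state == "PRO" else "abundance_qui"]

    @property
    def true_log2_fc(self) -> pd.Series:
        return self.table["true_log2_fc"]


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], pd.DataFrame, list[ArrayProbe], list[ExpressionProbe]]:
    """Generate the toy genome, annotation table, and both probe sets.

    Returns ``(genome, annotations, array_probes, seq_probes)``. Transcripts
    are embedded in the chromosomes separated by random intergenic spacers;
    coordinates are 1-based inclusive. Array probes split into three groups
    of fixed sizes derived from the config fractions: plain probes (a
    substring of their source transcript, half of them reverse-complemented),
    ID-fallback probes (sequence absent from the genome, transcript ID kept),
    and decoys (sequence absent, no IDs).
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_GENOME)
    lo, hi = config.transcript_length_range

    # transcripts and chromosome assembly (round-robin chromosome assignment)
    tx_seqs: list[str] = []
    tx_records = []
    chrom_parts: dict[str, list[str]] = {
        f"chr{i + 1}": [] for i in range(config.n_chromosomes)
    }
    chrom_pos = {name: 0 for name in chrom_parts}
    for i in range(config.n_transcripts):
        tid = f"ENST{i + 1:011d}"
        chrom = f"chr{(i % config.n_chromosomes) + 1}"
        length = int(rng.integers(lo, hi + 1))
        spacer = _random_sequence(rng, int(rng.integers(50, 201)))
        seq = _random_sequence(rng, length)
        chrom_parts[chrom].append(spacer)
        chrom_pos[chrom] += len(spacer)
        start = chrom_pos[chrom] + 1
        chrom_parts[chrom].append(seq)
        chrom_pos[chrom] += length
        end = chrom_pos[chrom]
        tx_seqs.append(seq)
        tx_records.append(
            {"transcript_id": tid, "chromosome": chrom, "start": start, "end": end,
             "strand": "+"}
        )
    genome = {name: "".join(parts) for name, parts in chrom_parts.items()}
    annotations = pd.DataFrame(tx_records)

    seq_probes = feature_probes_from_annotation(annotations, genome)

    # array probe group sizes are fixed by the config, then shuffled over slots
    n = config.n_array_probes
    n_decoy = config.n_decoy_probes
    n_fallback = config.n_id_fallback_probes
    kinds = np.array(
        ["decoy"] * n_decoy + ["fallback"] * n_fallback
        + ["plain"] * (n - n_decoy - n_fallback)
    )
    rng.shuffle(kinds)

    def absent_kmer() -> str:
        # rejection-sample a k-mer absent from both strands of every chromosome
        while True:
            cand = _random_sequence(rng, config.array_probe_length)
            rc = reverse_complement(cand)
            if not any(cand in c or rc in c for c in genome.values()):
                return cand

    array_probes: list[ArrayProbe] = []
    L = config.array_probe_length
    for i, kind in enumerate(kinds):
        pid = f"AP{i + 1:05d}"
        if kind == "decoy":
            array_probes.append(
                ArrayProbe(pid, absent_kmer(), f"chr{int(rng.integers(config.n_chromosomes)) + 1}",
                           frozenset(), decoy=True)
            )
            continue
        t = int(rng.integers(config.n_transcripts))
        rec = tx_records[t]
        if kind == "fallback":
            seq = absent_kmer()
        else:
            off = int(rng.integers(0, len(tx_seqs[t]) - L + 1))
            seq = tx_seqs[t][off : off + L]
            if rng.random() < 0.5:  # antisense spotting
                seq = reverse_complement(seq)
        array_probes.append(
            ArrayProbe(pid, seq, rec["chromosome"],
                       frozenset({rec["transcript_id"]}), decoy=False)
        )
    return genome, annotations, array_probes, seq_probes


def array_probe_sources(
    array_probes: Sequence[ArrayProbe], seq_probes: Sequence[ExpressionProbe]
) -> dict[str, str]:
    """Ground-truth map array probe id -> source transcript id (non-decoys).

    The generator stamps each non-decoy probe with its source transcript's ID,
    so the true correspondence is recoverable without running the mapper.
    """
    return {
        p.probe_id: next(iter(p.ensembl_ids))
        for p in array_probes
        if not p.decoy and p.ensembl_ids
    }


#: tolerance (log2 units) on between-state total-output balance
_BALANCE_TOL = 0.005
_BALANCE_MAX_ATTEMPTS = 50_000


def simulate_expression(
    config: SimulationConfig, weights: np.ndarray | pd.Series | None = None
) -> GroundTruth:
    """Draw latent abundances for both states.

    Baseline log2 abundances are Normal(baseline_log2_mean, baseline_log2_sd).
    Exactly ``n_genes_changed`` transcripts (chosen uniformly) receive a true
    log2 FC of random sign with magnitude ``min_abs_log2_fc`` plus an
    exponential excess (mean 0.5 log2 units); all others have log2 FC 0.

    The two states conserve total transcriptional output: change assignments
    are rejection-sampled until the (optionally ``weights``-weighted, e.g. by
    transcript length) total abundance differs between states by less than
    0.005 log2 units. Quiescence thus redistributes the transcriptome rather
    than rescaling it, which keeps composition-normalized quantifications
    (RPKM) asymptotically unbiased for the true per-gene fold changes.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_EXPRESSION)
    n = config.n_transcripts
    ids = pd.Index([f"ENST{i + 1:011d}" for i in range(n)], name="transcript_id")
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    abundance = np.exp2(baseline)
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w <= 0).any():
            raise ValueError("weights must be positive, one per transcript")
    total = float((w * abundance).sum())

    log2_fc = np.zeros(n)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    if config.n_genes_changed > 0:
        for _ in range(_BALANCE_MAX_ATTEMPTS):
            changed = rng.choice(n, size=config.n_genes_changed, replace=False)
            signs = rng.choice([-1.0, 1.0], size=config.n_genes_changed)
            mags = config.min_abs_log2_fc + rng.exponential(
                0.5, size=config.n_genes_changed
            )
            fc = np.exp2(signs * mags)
            imbalance = abs(
                np.log2(1.0 + (w[changed] * abundance[changed] * (fc - 1.0)).sum() / total)
            )
            if best is None or imbalance < best[0]:
                best = (imbalance, changed, signs * mags)
            if imbalance <= _BALANCE_TOL:
                break
        _, changed, effects = best
        log2_fc[changed] = effects
    abundance_pro = abundance
    abundance_qui = abundance_pro * np.exp2(log2_fc)
    return GroundTruth(
        pd.DataFrame(
            {
                "abundance_pro": abundance_pro,
                "abundance_qui": abundance_qui,
                "true_log2_fc": log2_fc,
            },
            index=ids,
        )
    )


def simulate_microarray(
    truth: GroundTruth,
    array_probes: Sequence[ArrayProbe],
    orientation: str,
    config: SimulationConfig,
    array_index: int = 0,
) -> ArrayScan:
    """Two-channel intensities for one array under a dye orientation.

    Per non-decoy probe, each channel reads
    ``scale * abundance(state) * dye_bias(channel) * exp(eps)`` with
    eps ~ Normal(0, array_noise_sd^2), where the state-to-channel assignment
    follows ``orientation``. Decoy probes read background-only signal in both
    channels. Crosstalk then mixes the clean channels symmetrically:
    observed_A = clean_A + alpha * clean_B. ``array_index`` selects an
    independent noise stream per replicate array.
    """
    config.validate()
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    rng = _rng(config.seed, _STREAM_ARRAY, array_index)
    qui_channel = "cy5" if orientation == "qui-cy5" else "cy3"
    pro_channel = "cy3" if qui_channel == "cy5" else "cy5"

    pro_ab = truth.abundance("PRO")
    qui_ab = truth.abundance("QUI")
    base_pro = np.empty(len(array_probes))
    base_qui = np.empty(len(array_probes))
    for i, p in enumerate(array_probes):
        if p.decoy:
            base_pro[i] = base_qui[i] = config.array_background
            continue
        if not p.ensembl_ids:
            raise ValueError(
                f"probe {p.probe_id} has no source transcript and is not a decoy"
            )
        tid = next(iter(p.ensembl_ids))
        if tid not in truth.transcript_ids:
            raise ValueError(
                f"probe {p.probe_id}: source transcript {tid} absent from truth"
            )
        base_pro[i] = config.array_scale * pro_ab.loc[tid]
        base_qui[i] = config.array_scale * qui_ab.loc[tid]

    if config.array_noise_sd > 0:
        eps = rng.normal(0.0, config.array_noise_sd, size=(len(array_probes), 2))
    else:
        eps = np.zeros((len(array_probes), 2))
    bias = {"cy3": config.dye_bias_cy3, "cy5": config.dye_bias_cy5}
    chan = {
        pro_channel: base_pro * bias[pro_channel] * np.exp(eps[:, 0]),
        qui_channel: base_qui * bias[qui_channel] * np.exp(eps[:, 1]),
    }
    df = pd.DataFrame(
        {"cy3": chan["cy3"], "cy5": chan["cy5"]},
        index=pd.Index([p.probe_id for p in array_probes], name="probe_id"),
    )

    a = config.crosstalk_alpha
    mixed = df.copy()
    mixed["cy3"] = df["cy3"] + a * df["cy5"]
    mixed["cy5"] = df["cy5"] + a * df["cy3"]
    mixed["excluded"] = False
    return ArrayScan(f"QP{array_index + 1}", orientation, mixed)


def simulate_rnaseq_counts(
    truth: GroundTruth,
    seq_probes: Sequence[ExpressionProbe],
    library_size: int,
    nb_dispersion: float,
    seed_stream: tuple[int, ...],
    state: str,
    config: SimulationConfig,
    sample: str,
) -> CountTable:
    """Per-probe read counts for one replicate of one state.

    Expected counts are proportional to abundance x probe length, scaled so
    the expected total equals ``library_size``. Counts are negative binomial
    with the given dispersion d (variance mu + d*mu^2), via a gamma-Poisson
    mixture; dispersion 0 gives Poisson.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    rng = _rng(config.seed, _STREAM_RNASEQ, *seed_stream)
    ab = truth.abundance(state)
    weights = np.array([ab.loc[p.ensembl_id] * p.length for p in seq_probes], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all abundances are zero; cannot assign reads")
    mu = library_size * weights / total
    if nb_dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / nb_dispersion
        lam = np.where(mu > 0, rng.gamma(shape, 1.0, size=mu.size) * mu / shape, 0.0)
        counts = rng.poisson(lam)
    return count_table_from_probes(sample, seq_probes, counts)


def simulate_qpcr(
    truth: GroundTruth,
    genes: Sequence[str],
    normalizer_genes: Sequence[str],
    config: SimulationConfig,
) -> pd.DataFrame:
    """CT values for target and normalizer genes in both states.

    CT = intercept + slope * log2(abundance) + Normal(0, ct_noise_sd^2), one
    row per (gene, state, replicate). Normalizer genes must have a true log2
    FC of zero (they are the stable references the ddCT method assumes).
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_QPCR)
    for g in list(genes) + list(normalizer_genes):
        if g not in truth.transcript_ids:
            raise ValueError(f"gene {g} absent from the simulated truth")
    for g in normalizer_genes:
        if truth.true_log2_fc.loc[g] != 0.0:
            raise ValueError(f"normalizer gene {g} has nonzero true fold change")
    rows = []
    for g in list(dict.fromkeys(list(genes) + list(normalizer_genes))):
        for state in ("PRO", "QUI"):
            mean_ct = config.qpcr_intercept + config.qpcr_slope * float(
                np.log2(truth.abundance(state).loc[g])
            )
            for rep in range(1, config.n_qpcr_replicates + 1):
                noise = (
                    rng.normal(0.0, config.qpcr_ct_noise_sd)
                    if config.qpcr_ct_noise_sd > 0
                    else 0.0
                )
                rows.append(
                    {"gene": g, "state": state, "replicate": rep, "ct": mean_ct + noise}
                )
    return pd.DataFrame(rows, columns=["gene", "state", "replicate", "ct"])


def pick_qpcr_panel(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[list[str], list[str]]:
    """Choose target genes (half changed, half unchanged) and 4 stable normalizers."""
    rng = _rng(config.seed, _STREAM_QPCR, 99)
    changed = [t for t in truth.transcript_ids if truth.true_log2_fc.loc[t] != 0.0]
    stable = [t for t in truth.transcript_ids if truth.true_log2_fc.loc[t] == 0.0]
    if len(stable) < 4:
        raise ValueError("need at least 4 unchanged transcripts for normalizers")
    normalizers = [stable[i] for i in sorted(rng.choice(len(stable), 4, replace=False))]
    pool_stable = [s for s in stable if s not in normalizers]
    n_changed = min(len(changed), config.n_qpcr_genes // 2)
    n_stable = min(len(pool_stable), config.n_qpcr_genes - n_changed)
    targets = [changed[i] for i in sorted(rng.choice(len(changed), n_changed, replace=False))]
    targets += [pool_stable[i] for i in sorted(rng.choice(len(pool_stable), n_stable, replace=False))]
    return targets, normalizers
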
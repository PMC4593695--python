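"""End-to-end orchestration: simulate -> normalize -> map -> concordance -> qPCR.

Stages hand off through flat files (FASTA/TSV/JSON) under one output
directory, so each stage can be rerun and inspected on its own, and a run
manifest records the config snapshot and a checksum of every artifact;
rerunning with the same config reproduces identical bytes.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .arrays import (
    ArrayScan,
    array_fold_changes,
    combine_arrays_geometric_mean,
    cross_channel_correct,
    lowess_normalize,
)
from .config import SimulationConfig, write_config
from .foldchange import FoldChangeTable
from .io import write_annotations, write_fasta
from .mapping import mapping_summary, resolve_mapping
from .probes import write_array_probes, write_expression_probes
from .qpcr import gene_level_array_fc, platform_agreement, qpcr_fold_changes
from .seq import pool_replicates, rpkm_normalize, seq_fold_changes
from .simulate import (
    array_probe_sources,
    pick_qpcr_panel,
    simulate_expression,
    simulate_genome,
    simulate_microarray,
    simulate_qpcr,
    simulate_rnaseq_counts,
)
from .stats import (
    overlap_null_distribution,
    overlap_permutation_test,
    pairwise_correlations,
    reproducibility_report,
    threshold_concordance,
    top_k_list,
)

log = logging.getLogger("concordia")

DEFAULT_ORIENTATIONS = ("qui-cy5", "qui-cy3", "qui-cy5", "qui-cy3")
DEFAULT_TOP_K = (10, 50, 100, 500, 1000)
DEFAULT_FC_THRESHOLD = 5.0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunResult:
    """In-memory handles on the main outputs of a full run."""

    outdir: Path
    mapping_summary: dict
    cross_platform: pd.DataFrame
    array_reproducibility: pd.DataFrame
    seq_reproducibility: pd.DataFrame
    overlap_tests: pd.DataFrame
    threshold_concordance: pd.DataFrame
    qpcr_agreement: dict
    manifest: dict


def run_full_analysis(
    config: SimulationConfig,
    outdir: str | Path,
    orientations: Sequence[str] = DEFAULT_ORIENTATIONS,
    top_k: Sequence[int] = DEFAULT_TOP_K,
    n_trials: int = 2000,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    pseudocount: float = 0.05,
) -> RunResult:
    """Run the whole synthetic study and write a report bundle under ``outdir``.

    Produces: the toy genome and probe files; per-array normalized
    intensities and fold changes; pooled RNA-seq RPKM tables and fold
    changes; the probe mapping with its summary; replicate-reproducibility
    and cross-platform correlation grids; top-k overlap permutation tests in
    both directions; fold-change threshold concordance; the qPCR ddCT
    adjudication; and a manifest with SHA-256 checksums of every artifact.
    List sizes in ``top_k`` exceeding the mapped universe are skipped.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("stage=simulate seed=%d", config.seed)
    genome, annotations, array_probes, seq_probes = simulate_genome(config)
    lengths = (annotations["end"] - annotations["start"] + 1).to_numpy()
    truth = simulate_expression(config, weights=lengths)
    write_fasta(genome, outdir / "genome.fa")
    write_annotations(annotations, outdir / "annotations.tsv")
    write_array_probes(array_probes, outdir / "array_probes.tsv")
    write_expression_probes(seq_probes, outdir / "seq_probes.tsv")
    write_config(config, outdir / "config.txt")
    truth.table.to_csv(outdir / "ground_truth.tsv", sep="\t")

    # ---- microarrays ----------------------------------------------------
    array_fc: dict[str, FoldChangeTable] = {}
    array_scans: dict[str, ArrayScan] = {}
    for i, orient in enumerate(orientations):
        scan = simulate_microarray(truth, array_probes, orient, config, array_index=i)
        scan.to_tsv(outdir / f"{scan.array_id}_raw.tsv")
        scan = cross_channel_correct(scan, config.crosstalk_alpha)
        scan = lowess_normalize(scan)
        scan.to_tsv(outdir / f"{scan.array_id}_normalized.tsv")
        array_scans[scan.array_id] = scan
        fc = array_fold_changes(scan)
        fc.to_tsv(outdir / f"{scan.array_id}_fc.tsv")
        array_fc[scan.array_id] = fc
        log.info("stage=array array=%s orientation=%s probes=%d",
                 scan.array_id, orient, len(fc))
    combined = combine_arrays_geometric_mean(list(array_fc.values()), source="all")
    combined.to_tsv(outdir / "array_combined_fc.tsv")

    # ---- RNA-seq --------------------------------------------------------
    tables = {}
    for state in ("PRO", "QUI"):
        for rep, lib in enumerate(config.library_sizes, start=1):
            sample = f"{state}{rep}"
            t = simulate_rnaseq_counts(
                truth, seq_probes, lib, config.nb_dispersion,
                seed_stream=(rep, 0 if state == "PRO" else 1), state=state,
                config=config, sample=sample,
            )
            tables[sample] = rpkm_normalize(t)
            tables[sample].to_tsv(outdir / f"counts_{sample}.tsv")
    pooled_pro = pool_replicates(tables["PRO1"], tables["PRO2"], sample="PRO")
    pooled_qui = pool_replicates(tables["QUI1"], tables["QUI2"], sample="QUI")
    seq_fc = seq_fold_changes(pooled_pro, pooled_qui, pseudocount, source="rnaseq")
    seq_fc.to_tsv(outdir / "rnaseq_fc.tsv")
    rep_fc = {
        "QUI1/PRO1": seq_fold_changes(tables["PRO1"], tables["QUI1"], pseudocount,
                                      source="QUI1/PRO1"),
        "QUI2/PRO2": seq_fold_changes(tables["PRO2"], tables["QUI2"], pseudocount,
                                      source="QUI2/PRO2"),
    }

    # ---- probe mapping --------------------------------------------------
    mapping = resolve_mapping(array_probes, seq_probes)
    mapping.to_tsv(outdir / "probe_mapping.tsv")
    summary = mapping_summary(mapping)
    summary.to_json(outdir / "mapping_summary.json")
    log.info("stage=mapping mapped=%d/%d (%d%%)", summary.n_mapped,
             summary.n_array_probes, summary.percent_mapped)

    # restrict both platforms to the mapped correspondence
    pairs = mapping.entries["seq_probe_id"]
    universe = sorted(set(pairs))
    universe_size = len(universe)

    def array_fc_on_universe(fc: FoldChangeTable, label: str) -> FoldChangeTable:
        # re-key array probes by their mapped feature probe; where several
        # array probes hit one feature probe, combine by geometric mean
        mapped = pairs.reindex(fc.fc.index).dropna()
        grouped = np.log2(fc.fc.reindex(mapped.index)).groupby(mapped).mean()
        return FoldChangeTable(label, np.exp2(grouped))

    cross_sources = {k: array_fc_on_universe(v, k) for k, v in array_fc.items()}
    cross_sources["all"] = array_fc_on_universe(combined, "all")
    seq_on_universe = FoldChangeTable("rnaseq", seq_fc.fc.reindex(universe).dropna())

    # ---- concordance report ---------------------------------------------
    array_repro = reproducibility_report(array_fc)
    array_repro.to_csv(outdir / "table1_array_reproducibility.tsv", sep="\t", index=False)
    seq_repro = reproducibility_report(rep_fc)
    seq_repro.to_csv(outdir / "table2_seq_reproducibility.tsv", sep="\t", index=False)

    cross_rows = []
    for label, fc in cross_sources.items():
        triples = pairwise_correlations({"rnaseq": seq_on_universe.fc, label: fc.fc})
        c = next(iter(triples.values()))
        cross_rows.append(
            {"array_source": label, "pearson": c.pearson,
             "pearson_log2": c.pearson_log2, "spearman": c.spearman, "n": c.n}
        )
    cross = pd.DataFrame(cross_rows)
    cross.to_csv(outdir / "table3_cross_platform_fc.tsv", sep="\t", index=False)

    overlap_rows = []
    usable_k = [k for k in top_k if k <= universe_size]
    for k in usable_k:
        null = overlap_null_distribution(k, universe_size, n_trials, seed=config.seed + k)
        for direction in ("highest", "lowest"):
            seq_list = top_k_list(seq_on_universe, k, direction)
            for label, fc in cross_sources.items():
                res = overlap_permutation_test(
                    seq_list, top_k_list(fc, k, direction), universe_size,
                    n_trials=n_trials, seed=config.seed + k, null=null,
                )
                overlap_rows.append(
                    {"k": k, "direction": direction, "array_source": label,
                     "n_observed": res.n_observed, "p_value": res.p_value,
                     "n_trials": res.n_trials}
                )
    overlaps = pd.DataFrame(overlap_rows)
    overlaps.to_csv(outdir / "table4_overlap_tests.tsv", sep="\t", index=False)

    thr_rows = []
    for label, fc in cross_sources.items():
        t = threshold_concordance(fc, seq_on_universe, fc_threshold)
        thr_rows.append(
            {"array_source": label, "threshold": t.threshold, "n_array_above": t.n_a_above,
             "n_both_above": t.n_both_above, "percent": t.percent}
        )
    thresholds = pd.DataFrame(thr_rows)
    thresholds.to_csv(outdir / "threshold_concordance.tsv", sep="\t", index=False)

    # ---- qPCR arbitration ------------------------------------------------
    targets, normalizers = pick_qpcr_panel(truth, config)
    ct = simulate_qpcr(truth, targets, normalizers, config)
    ct.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    fc_qpcr = qpcr_fold_changes(ct, normalizers)

    sources = array_probe_sources(array_probes, seq_probes)
    seq_probe_by_tid = {p.ensembl_id: p.probe_id for p in seq_probes}
    rows = []
    for g in fc_qpcr.index:
        rp = seq_probe_by_tid.get(g)
        if rp is None or rp not in seq_fc.fc.index:
            continue
        probe_fcs = [
            combined.fc.loc[ap]
            for ap, tid in sources.items()
            if tid == g and ap in combined.fc.index
        ]
        if not probe_fcs:
            continue
        rows.append(
            {"gene": g, "fc_qpcr": fc_qpcr.loc[g], "fc_rnaseq": seq_fc.fc.loc[rp],
             "fc_array": gene_level_array_fc(probe_fcs)}
        )
    gene_df = pd.DataFrame(rows).set_index("gene")
    gene_df.to_csv(outdir / "table5_gene_fold_changes.tsv", sep="\t")
    agreement = platform_agreement(gene_df)
    qpcr_summary = {
        "n_genes": agreement.n_genes,
        "normalizers": list(normalizers),
        "qpcr_vs_rnaseq": agreement.qpcr_vs_rnaseq.__dict__,
        "qpcr_vs_array": agreement.qpcr_vs_array.__dict__,
        "n_rnaseq_closer": agreement.n_rnaseq_closer,
        "n_array_closer": agreement.n_array_closer,
        "n_ties": agreement.n_ties,
    }
    (outdir / "qpcr_agreement.json").write_text(json.dumps(qpcr_summary, indent=2) + "\n")

    # ---- manifest --------------------------------------------------------
    artifacts = sorted(p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "orientations": list(orientations),
        "swapped_arrays": [f"QP{i + 1}" for i, o in enumerate(orientations)
                           if o == "qui-cy3"],
        "n_trials": n_trials,
        "top_k": list(usable_k),
        "fc_threshold": fc_threshold,
        "pseudocount": pseudocount,
        "checksums": {p.name: _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return RunResult(
        outdir=outdir,
        mapping_summary=summary.__dict__,
        cross_platform=cross,
        array_reproducibility=array_repro,
        seq_reproducibility=seq_repro,
        overlap_tests=overlaps,
        threshold_concordance=thresholds,
        qpcr_agreement=qpcr_summary,
        manifest=manifest,
    )
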
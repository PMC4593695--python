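"""The synthetic study generator: determinism, structure, noise-free limits."""
import numpy as np
import pandas as pd
import pytest

from concordia import (
    SimulationConfig,
    array_fold_changes,
    array_probe_sources,
    reverse_complement,
    rpkm_normalize,
    simulate_expression,
    simulate_genome,
    simulate_microarray,
    simulate_qpcr,
    simulate_rnaseq_counts,
)
from concordia.io import write_fasta


def test_probe_group_sizes_follow_config(small_config, small_world):
    genome, annotations, array_probes, seq_probes = small_world
    assert len(seq_probes) == small_config.n_transcripts
    assert len(array_probes) == small_config.n_array_probes
    assert sum(p.decoy for p in array_probes) == small_config.n_decoy_probes


def test_decoy_sequences_absent_from_genome(small_world):
    genome, _, array_probes, _ = small_world
    for p in array_probes:
        if p.decoy:
            for chrom_seq in genome.values():
                assert p.sequence not in chrom_seq
                assert reverse_complement(p.sequence) not in chrom_seq


def test_nondecoy_plain_probes_are_transcript_substrings(small_world):
    """Brute-force substring check of each probe against its source transcript span."""
    genome, annotations, array_probes, _ = small_world
    ann = annotations.set_index("transcript_id")
    n_checked = 0
    for p in array_probes:
        if p.decoy or not p.ensembl_ids:
            continue
        tid = next(iter(p.ensembl_ids))
        rec = ann.loc[tid]
        tx_seq = genome[rec["chromosome"]][rec["start"] - 1 : rec["end"]]
        if p.sequence in tx_seq or reverse_complement(p.sequence) in tx_seq:
            n_checked += 1
    # everything except decoys and the scrambled ID-fallback probes matches
    cfg_expected = (
        len(array_probes)
        - sum(p.decoy for p in array_probes)
        - round(0.05 * len(array_probes))  # id_fallback_fraction of the fixture
    )
    assert n_checked == cfg_expected


def test_genome_generation_is_deterministic(small_config, small_world):
    genome2, ann2, probes2, seq2 = simulate_genome(small_config)
    genome, ann, probes, seq = small_world
    # byte-identical FASTA output on a rerun with the same config
    import pathlib
    import tempfile
    with tempfile.TemporaryDirectory() as d:
        p1, p2 = pathlib.Path(d) / "a.fa", pathlib.Path(d) / "b.fa"
        write_fasta(genome, p1)
        write_fasta(genome2, p2)
        assert p1.read_bytes() == p2.read_bytes()
    assert probes == probes2
    pd.testing.assert_frame_equal(ann, ann2)


def test_expression_changed_gene_count_is_exact():
    cfg = SimulationConfig(n_transcripts=40, n_genes_changed=7, n_array_probes=50)
    for seed in range(20):
        truth = simulate_expression(cfg.with_(seed=seed))
        changed = truth.true_log2_fc[truth.true_log2_fc != 0]
        assert len(changed) == 7
        assert (np.abs(changed) >= cfg.min_abs_log2_fc - 1e-12).all()


def test_expression_no_changes_all_zero():
    cfg = SimulationConfig(n_transcripts=30, n_genes_changed=0, n_array_probes=40)
    truth = simulate_expression(cfg)
    assert (truth.true_log2_fc == 0).all()


def test_truth_fold_change_identity(small_truth):
    ratio = np.log2(small_truth.table["abundance_qui"] / small_truth.table["abundance_pro"])
    np.testing.assert_allclose(ratio, small_truth.true_log2_fc, atol=1e-9)


def test_noise_free_microarray_recovers_truth(clean_config, small_world, small_truth):
    _, _, array_probes, _ = small_world
    scan = simulate_microarray(small_truth, array_probes, "qui-cy5", clean_config)
    fc = array_fold_changes(scan)
    sources = array_probe_sources(array_probes, [])
    for pid, tid in sources.items():
        assert fc.log2_fc.loc[pid] == pytest.approx(
            small_truth.true_log2_fc.loc[tid], abs=1e-9
        )


def test_dye_swapped_arrays_have_reciprocal_channel_ratios(clean_config, small_world, small_truth):
    """Noise-free dye swap inverts the cy5/cy3 ratio probe by probe, while the
    orientation-aware QUI/PRO fold change is identical on both arrays."""
    _, _, array_probes, _ = small_world
    a = simulate_microarray(small_truth, array_probes, "qui-cy5", clean_config, 0)
    b = simulate_microarray(small_truth, array_probes, "qui-cy3", clean_config, 0)
    ratio_a = a.data["cy5"] / a.data["cy3"]
    ratio_b = b.data["cy5"] / b.data["cy3"]
    np.testing.assert_allclose(ratio_a, 1.0 / ratio_b, rtol=1e-9)
    np.testing.assert_allclose(
        array_fold_changes(a).fc, array_fold_changes(b).fc, rtol=1e-9
    )


def test_rnaseq_counts_deterministic_and_integer(small_config, small_world, small_truth):
    _, _, _, seq_probes = small_world
    t1 = simulate_rnaseq_counts(small_truth, seq_probes, 50_000, 0.1, (1, 0), "PRO",
                                small_config, "PRO1")
    t2 = simulate_rnaseq_counts(small_truth, seq_probes, 50_000, 0.1, (1, 0), "PRO",
                                small_config, "PRO1")
    pd.testing.assert_frame_equal(t1.data, t2.data)
    assert (t1.data["raw_count"] >= 0).all()
    assert t1.data["raw_count"].dtype.kind == "i"


def test_rnaseq_zero_abundance_gives_zero_counts(small_config, small_world, small_truth):
    _, _, _, seq_probes = small_world
    truth = small_truth.table.copy()
    dead = truth.index[0]
    truth.loc[dead, ["abundance_pro", "abundance_qui"]] = 0.0
    from concordia import GroundTruth
    t = simulate_rnaseq_counts(GroundTruth(truth), seq_probes, 100_000, 0.2, (0,), "PRO",
                               small_config, "x")
    assert t.data.loc[f"RP_{dead}", "raw_count"] == 0


def test_rnaseq_negative_dispersion_rejected(small_config, small_world, small_truth):
    _, _, _, seq_probes = small_world
    with pytest.raises(ValueError, match="dispersion"):
        simulate_rnaseq_counts(small_truth, seq_probes, 1000, -0.1, (0,), "PRO",
                               small_config, "x")


def test_rnaseq_rpkm_tracks_abundance_at_large_library(small_config, small_world, small_truth):
    """Law of large numbers: RPKM / abundance is constant across probes."""
    _, _, _, seq_probes = small_world
    t = simulate_rnaseq_counts(small_truth, seq_probes, 1_000_000, 0.0, (7,), "PRO",
                               small_config, "big")
    rpkm = rpkm_normalize(t).rpkm
    ab = small_truth.abundance("PRO")
    ratios = np.array([rpkm.loc[p.probe_id] / ab.loc[p.ensembl_id] for p in seq_probes])
    counts = t.data["raw_count"].to_numpy()
    keep = counts >= 50  # exclude probes whose Poisson error still dominates
    rel_spread = np.std(ratios[keep]) / np.mean(ratios[keep])
    assert rel_spread < 0.05


def test_qpcr_noise_free_normalizers_have_equal_delta_ct(clean_config, small_truth):
    stable = [t for t in small_truth.transcript_ids if small_truth.true_log2_fc.loc[t] == 0][:4]
    ct = simulate_qpcr(small_truth, [], stable, clean_config)
    mean_ct = ct.groupby(["gene", "state"])["ct"].mean().unstack("state")
    for a in stable:
        for b in stable:
            d_pro = mean_ct.loc[a, "PRO"] - mean_ct.loc[b, "PRO"]
            d_qui = mean_ct.loc[a, "QUI"] - mean_ct.loc[b, "QUI"]
            assert d_pro == pytest.approx(d_qui, abs=1e-9)


def test_qpcr_changed_normalizer_rejected(clean_config, small_truth):
    changed = [t for t in small_truth.transcript_ids
               if small_truth.true_log2_fc.loc[t] != 0][:1]
    with pytest.raises(ValueError, match="normalizer"):
        simulate_qpcr(small_truth, [], changed, clean_config)


def test_qpcr_unknown_gene_rejected(clean_config, small_truth):
    with pytest.raises(ValueError, match="absent"):
        simulate_qpcr(small_truth, ["ENSTnope"], [], clean_config)
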
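"""ddCT relative quantification against a normalizer panel.

Simulates noise-free CT values, recovers each gene's fold change by the
2^-ddCT rule averaged over four stable normalizer genes, and shows the
platform adjudication on a three-platform gene table.
"""
import pandas as pd

from concordia import (
    SimulationConfig,
    platform_agreement,
    qpcr_fold_changes,
    simulate_expression,
    simulate_qpcr,
)

cfg = SimulationConfig(seed=11, n_transcripts=100, n_array_probes=120,
                       qpcr_ct_noise_sd=0.0)
truth = simulate_expression(cfg)
stable = [t for t in truth.transcript_ids if truth.true_log2_fc[t] == 0][:4]
targets = [t for t in truth.transcript_ids if truth.true_log2_fc[t] != 0][:5]

ct = simulate_qpcr(truth, targets, stable, cfg)
fc = qpcr_fold_changes(ct, normalizer_genes=stable)
print("gene              ddCT fold change    true fold change")
for g in targets:
    print(f"{g}   {fc[g]:16.3f}    {2 ** truth.true_log2_fc[g]:16.3f}")

genes = pd.DataFrame(
    {"fc_qpcr": fc[targets], "fc_rnaseq": fc[targets] * 1.05, "fc_array": fc[targets] * 1.6}
)
ag = platform_agreement(genes)
print(f"\nRNA-seq closer for {ag.n_rnaseq_closer} genes, "
      f"microarray closer for {ag.n_array_closer}, ties {ag.n_ties}.")
print("With noise-free CT values the ddCT inversion is exact, so the first two"
      "\ncolumns agree; the adjudication compares each platform's log2 FC"
      "\ndistance to the qPCR reference.")
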
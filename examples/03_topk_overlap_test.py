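"""Top-k overlap permutation test with its exact hypergeometric cross-check.

Builds two noisy measurements of the same fold-change vector, takes each
platform's top-10 list, and asks how surprising their overlap is under
random k-subsets of the shared probe universe.
"""
import numpy as np
import pandas as pd

from concordia import (
    FoldChangeTable,
    overlap_exact_pvalue,
    overlap_permutation_test,
    top_k_list,
)

rng = np.random.default_rng(5)
n = 300
ids = [f"p{i:04d}" for i in range(n)]
true_log2 = np.where(np.arange(n) < 20, 3.0, 0.0)  # 20 genuinely changed probes
fc_a = FoldChangeTable("platform_a", pd.Series(np.exp2(true_log2 + rng.normal(0, 0.8, n)), index=ids))
fc_b = FoldChangeTable("platform_b", pd.Series(np.exp2(true_log2 + rng.normal(0, 0.8, n)), index=ids))

k = 10
list_a = top_k_list(fc_a, k, "highest")
list_b = top_k_list(fc_b, k, "highest")
res = overlap_permutation_test(list_a, list_b, universe_size=n, n_trials=10_000, seed=1)
print(f"top-{k} overlap n = {res.n_observed}")
print(f"empirical p (10,000 trials) = {res.p_value:.4f}")
print(f"exact hypergeometric tail   = {overlap_exact_pvalue(k, res.n_observed, n):.2e}")
print(
    "\nThe p-value is the share of trials in which two random 10-probe lists"
    "\nshared at least as many probes; agreement with the closed-form tail"
    "\nshows the permutation machinery is calibrated."
)
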
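#!/usr/bin/env python
"""Replicate reproducibility: gene-level RPM correlations and the
counting-statistics floor.

Reports Pearson correlations between replicate libraries, the replicate
error sigma (std of log2 site-coverage ratios, as a fold), and compares the
observed replicate-fraction spread against the binomial-partitioning
prediction 1/(2 sqrt N). Writes results/reproducibility.tsv.
"""

import os
import sys

import numpy as np
import pandas as pd

from xlinkscape import compute_library_table, replicate_correlation
from xlinkscape.differential import replicate_fraction_std, replicate_sigma
from xlinkscape.pipeline import run_pipeline
from xlinkscape.studies import differential_params, reproducibility_config
from xlinkscape.synthetic_data import simulate_study

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main(seed: int = 1):
    config = reproducibility_config(seed)
    genome, transcripts, truth, libs = simulate_study(config)
    rows = []
    for kind in ("mrnaseq", "gparclip"):
        t1 = compute_library_table(libs[(kind, "WT", 1)], transcripts)
        t2 = compute_library_table(libs[(kind, "WT", 2)], transcripts)
        r = replicate_correlation(t1, t2)
        rows.append((f"{kind}_rpm_pearson", r))
        print(f"{kind} WT replicate gene-RPM Pearson r = {r:.4f}")

    result = run_pipeline(libs, transcripts, genome)
    sigma, fold = replicate_sigma(
        result.matrix, "gparclip_WT_rep1", "gparclip_WT_rep2",
        min_rpm=differential_params(config).min_rpm)
    rows.append(("sigma_log2", sigma))
    rows.append(("fold_sigma", fold))
    print(f"replicate error sigma = {fold:.2f}-fold "
          f"(std of log2 ratios {sigma:.3f}) over "
          f"{result.matrix.mean_rpm.shape[0]} sites")

    stats = replicate_fraction_std(result.matrix, "gparclip_WT_rep1",
                                   "gparclip_WT_rep2")
    for lo, obs, pred, n in zip(stats.bin_edges, stats.observed_std,
                                stats.predicted_std, stats.n_sites):
        if not np.isnan(obs):
            rows.append((f"fraction_std_obs_bin{lo:g}", obs))
            rows.append((f"fraction_std_binomial_bin{lo:g}", pred))

    os.makedirs(RESULTS, exist_ok=True)
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(
        os.path.join(RESULTS, "reproducibility.tsv"), sep="\t", index=False)
    print("wrote results/reproducibility.tsv")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
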
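"""Simulate a planted 78-sample compendium and run expression prep.

Generates a small synthetic FPKM-like matrix (8 ordered tissue groups,
one planted collaborative TF module), applies the >92%-zeros gene filter
and the log2(FPKM+1) transform, and prints the resulting dimensions.
"""
import numpy as np

from tfcollab import (SyntheticConfig, PlantedModule, make_expression,
                      filter_sparse_genes, log_transform,
                      group_factor_profile, DEFAULT_GROUP_SIZES)

factor = group_factor_profile(DEFAULT_GROUP_SIZES, [2, 2, 5, 5, 6, 3, 2, 2])
module = PlantedModule(tf_ids=["TF001", "TF002", "TF003"],
                       ccg_ids=[f"G{i:04d}" for i in range(1, 21)],
                       factor_profile=factor, loading_sd=0.1)
cfg = SyntheticConfig(n_genes=200, n_tfs=10, modules=[module],
                      noise_sd=0.5, zero_inflation=0.05, seed=7)
X, truth = make_expression(cfg)
print(f"simulated matrix: {X.n_genes} genes x {X.n_samples} samples "
      f"({len(X.group_order)} tissue groups)")

Xf = filter_sparse_genes(X, max_zero_frac=0.92)
print(f"after sparsity filter: {Xf.n_genes} genes kept "
      f"({X.n_genes - Xf.n_genes} dropped for >92% zeros)")

Xl = log_transform(Xf)
members = Xl.values.loc[["TF001", "TF002", "TF003"]].to_numpy()
corr = np.corrcoef(members)[np.triu_indices(3, 1)].mean()
# planted module members share one latent factor, so their log-scale
# correlation is high; background pairs sit near zero
print(f"mean within-module correlation (log scale): {corr:.3f}")
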
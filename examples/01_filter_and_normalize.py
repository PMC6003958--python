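"""Counts-per-million normalisation and low-expression filtering.

Builds a small synthetic count matrix, normalises each sample to cpm
(count / library size x 1e6) and removes genes that are not strictly above
5 cpm in every sample — the standard floor below which correlation
estimates are dominated by sampling noise.
"""

from coexnet import cpm_normalize, filter_low_expression
from coexnet.simulate import SyntheticConfig, generate_modular_counts

cm, _ = generate_modular_counts(SyntheticConfig(n_genes=3000, rng_seed=0))
print(f"raw matrix: {len(cm.gene_ids)} genes x {len(cm.sample_ids)} samples")
print(f"library sizes: {cm.library_sizes.min()}-{cm.library_sizes.max()} reads")

nm = cpm_normalize(cm)
print(f"cpm column sums (should all be 1e6): "
      f"{nm.cpm.sum(axis=0).round(6).unique()}")

retained, nm_f = filter_low_expression(nm, min_cpm=5.0)
print(f"genes with cpm > 5 in all {len(cm.sample_ids)} samples: "
      f"{len(retained)} of {len(cm.gene_ids)}")
# The removed genes sit near the sequencing-noise floor; keeping them would
# flood the association matrix with unstable correlations.
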
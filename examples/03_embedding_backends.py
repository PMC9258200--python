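"""Embed a gene's variants with all three backends and compare separation.

lcw_sg walks the network and trains SkipGram on the walks; gmf_pca and
gmf_nmf factorize the association matrix globally. Separation is summarised
as the ratio of mean between-group to mean within-group embedding distance
for the planted module vs background (higher = cleaner separation).
"""

import numpy as np

import varmodnet as vm

gene = "GENE1"
order = vm.default_variant_names(gene, 12)
spec = vm.PlantedModuleSpec(gene, order[:8], 0.6, 0.05, 0.9, 0.02)
config = vm.SimulationConfig(2000, 0.1, [(gene, 12)], [spec], seed=0)
cohort, _ = vm.simulate_cohort(config)
ajm = vm.build_ajm(gene, order, cohort)

for backend in vm.BACKENDS:
    table = vm.embed(ajm, backend, seed=1)
    X = table.matrix(order)
    D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
    within = (D[:8, :8].sum() + D[8:, 8:].sum()) / (8 * 7 + 4 * 3)
    between = D[:8, 8:].mean()
    print(f"{backend:8s} dim={table.dim}  between/within distance ratio = {between/within:.2f}")
print("\nRatios well above 1 mean the backend places the planted module apart")
print("from the background; the global factorizations separate most cleanly.")
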
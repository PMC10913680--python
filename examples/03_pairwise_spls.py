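"""Pairwise sPLS integration of two omics blocks.

The Q² cross-validation rule picks the component count (last component with
total Q² above 0.0975 = 1 - 0.95²); the per-block keep counts are then
tuned by the correlation between CV-predicted and fitted component scores.
The thresholded similarity matrix yields a relevance network.
"""

import numpy as np

import holomix as hx

spec = hx.SyntheticSpec(
    classes=2, n_per_class=6, shared_factors=1, seed=3, class_separation=4.0,
    blocks=[hx.BlockSpec("metab", p=20, n_informative=6, loading_strength=3.0),
            hx.BlockSpec("transcripts", p=30, n_informative=6,
                         loading_strength=3.0)])
(X, Y), metadata, truth = hx.generate_multiomics(spec)

q2 = hx.q2_scores(X, Y, ncomp=3, folds=3, repeats=5, seed=3, mode="canonical")
ncomp = hx.select_ncomp_q2(q2)
print(f"total Q2 per component : {np.round(q2, 3)}")
print(f"components retained    : {ncomp}")

tune = hx.tune_spls_keep(X, Y, ncomp=ncomp, gridX=[3, 6, 12], gridY=[3, 6, 12],
                         folds=3, repeats=3, seed=3, mode="canonical")
model = hx.fit_spls(X, Y, ncomp=ncomp, keepX=tune.selected_keep["metab"],
                    keepY=tune.selected_keep["transcripts"], mode="canonical")
print(f"tuned keeps            : {tune.selected_keep}")

sim = hx.similarity_matrix(model, "metab", "transcripts")
net = hx.build_network(sim, cutoff=0.5, blocks=("metab", "transcripts"))
print(f"similarity range       : [{sim.to_numpy().min():.2f}, "
      f"{sim.to_numpy().max():.2f}]")
print(f"network at cutoff 0.5  : {net.n_nodes} nodes, {net.n_edges} edges")
print("\nEdges link features of different blocks whose absolute association"
      "\n(product of feature-score correlations) exceeds the cutoff.")
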
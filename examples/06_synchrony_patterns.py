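"""Multidimensional synchrony-pattern analysis of 32-D PLV vectors.

Group-structured synchrony vectors -> PCA -> 6-D projection -> within/
between-group distance statistics with permutation-calibrated flags.
"""
import numpy as np

from lfpsync.patterns import PatternDataset, fit_pca, group_distances, plot_embedding, project
from lfpsync.synth import gen_sync_vectors

rng = np.random.default_rng(0)
control = np.clip(rng.uniform(0.2, 0.7, 32), 0, 1)
lesion = np.clip(control - 0.15, 0, 1)     # globally weaker synchrony
treated = np.clip(control - 0.04, 0, 1)    # mostly restored

vectors = gen_sync_vectors(
    {"control": control, "lesion": lesion, "treated": treated},
    noise_sd=0.03, n_per_group=8, seed=6,
)
ds = PatternDataset.from_sync_vectors(vectors)
emb = fit_pca(ds)
print(f"variance explained by first 6 components: {emb.cumulative_variance(6):.3f}")

pts = project(emb, 6)
report = group_distances(pts, ds.labels, reference_group="control", seed=0)
print(f"within-group mean 6-D distances: "
      f"{ {g: round(v, 3) for g, v in report.within.items()} }")
cols = ["group", "cross_mean", "t", "p", "p_bonferroni", "significant"]
print(report.table[cols].to_string(index=False))
# the lesion cloud sits significantly farther from control than control's own
# spread; the treated cloud is closer and may not separate

plot_embedding(emb, "scratch_embedding.png")
print("wrote 3-D scatter of the first three components to scratch_embedding.png")
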
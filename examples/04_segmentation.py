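"""Automatic organ recognition from endogenous-metabolite profiles.

t-SNE embeds each pixel's 20-channel metabolite profile; k-means on the
embedding recovers the organ map without any manually drawn ROIs.  The
adjusted Rand index scores agreement with the ground-truth labels.
"""

from vcqmsi.msi_data import build_feature_table
from vcqmsi.pipeline import DEFAULT_DOSED_CONC
from vcqmsi.segmentation import cluster_pixels, embed_pixels, label_agreement
from vcqmsi.synthetic_data import PhantomSpec, generate_phantom

spec = PhantomSpec()
grid, truth = generate_phantom(spec, DEFAULT_DOSED_CONC, seed=101)
mask = truth.tissue_mask()
features = build_feature_table(grid, [f.mz for f in spec.endo_panel], mask=mask)

embedding = embed_pixels(features, grid.shape, perplexity=30, seed=17)
predicted = cluster_pixels(embedding, k=len(spec.organs), seed=17)
ari = label_agreement(predicted, truth.labels)

print(f"segmented {features.n_pixels} tissue pixels into "
      f"{len(spec.organs)} clusters")
print(f"adjusted Rand index vs ground-truth organs: {ari:.3f}")
# ARI of 1.0 means every organ is exactly one cluster; above ~0.9 the
# automatic segmentation can replace manual ROI drawing for region stats.
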
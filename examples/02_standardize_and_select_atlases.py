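"""Standardize intensities across a pool and select representative atlases.

The standard scale maps every image's within-mask intensity landmarks
(min, deciles, max) onto a population mean scale; selection then picks k
candidates spread "uniformly" over a PCA embedding of the standardized
images — centroid-closest first, then greedy farthest-point.
"""

import numpy as np

from segma import (PhantomParams, apply_standardization, embed_pool,
                   fit_standard_scale, generate_population, select_atlases)

population = generate_population(6, PhantomParams(shape=(32, 32, 32), seed=7))

model = fit_standard_scale(population.images, population.masks)
print("standard-scale landmarks:", np.round(model.landmarks, 1))

standardized = [apply_standardization(img, m, model)
                for img, _, m in population]

coords = embed_pool(standardized, population.masks)
print(f"embedding: {coords.shape[0]} subjects in {coords.shape[1]} dimensions")

selection = select_atlases(coords, k=3)
print("selected atlas indices (greedy order):", selection.indices)

# The first index is the subject closest to the population mean; the rest
# maximize spread, so the 3 atlases together cover the anatomy range.
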
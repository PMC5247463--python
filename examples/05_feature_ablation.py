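"""Measure feature-group importance by drop-one-group ablation.

The ten features partition into four groups (intensity, first-derivative
norms, gradient orientation, second-derivative norms).  Each run drops one
group and repeats the identical LOOCV.
"""

from segma import (PhantomParams, PipelineConfig, ablate_features,
                   generate_population)

population = generate_population(5, PhantomParams(shape=(32, 32, 32), seed=23))
table = ablate_features(population, config=PipelineConfig(k=3, seed=23))
print(table.round(2).to_string(index=False))

# Dropping intensity collapses accuracy: with piecewise-constant phantom
# tissue, intensity is by far the most informative feature.  The gradient
# groups matter at tissue boundaries, so their removal costs little on
# this small suite.
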
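"""Tune an extreme learning machine's hidden layer with AGOA on toy clusters."""

import numpy as np

from goaelm import agoa_config, predict, train_elm_agoa, train_elm_random
from goaelm.synthdata import FeatureDatasetSpec, generate_feature_dataset

ts = generate_feature_dataset(
    FeatureDatasetSpec(n_samples=100, n_features=5, class_separation=4.0, seed=3)
)

model, result = train_elm_agoa(
    ts, hidden_count=10,
    optimizer_config=agoa_config(population_size=15, max_iterations=30, rng_seed=3),
)
pred, _ = predict(model, ts.inputs)
print(f"AGOA-ELM training accuracy: {np.mean(pred == ts.class_labels):.3f}")
print(f"final training SSE (the optimized fitness): {result.best_fitness:.3f}")

baseline = train_elm_random(ts, hidden_count=10, seed=3)
bpred, _ = predict(baseline, ts.inputs)
print(f"random-weight ELM accuracy: {np.mean(bpred == ts.class_labels):.3f}")

# The optimizer searches over the hidden weights/biases only; the output
# weights are always the closed-form pseudoinverse solution.  The SSE is
# the sum of squared gaps between one-hot targets and network scores.
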
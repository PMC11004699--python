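"""Generate phantom images and push one through the convolutional stack."""

import tempfile
from pathlib import Path

from goaelm import ConvFeatureExtractor, preprocess_image
from goaelm.features import ConvStackConfig
from goaelm.synthdata import ImageDatasetSpec, generate_synthetic_images

print("layer output shapes:", ConvStackConfig().shape_chain())

with tempfile.TemporaryDirectory() as tmp:
    spec = ImageDatasetSpec(n_images=2, seed=0)
    manifest = generate_synthetic_images(spec, tmp)
    tensor = preprocess_image(Path(tmp) / manifest.loc[0, "filepath"])
    features = ConvFeatureExtractor(seed=0).extract(tensor)

print(f"preprocessed tensor shape: {tensor.shape}")
print(f"feature vector length: {features.size}, mean {features.mean():.4f}")

# The stack is the AlexNet convolutional geometry with seeded random
# unit-norm filters (a structured random projection): 227x227x3 in,
# 6x6x256 = 9216 features out, ready for the ELM classification head.
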
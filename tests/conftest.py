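import numpy as np
import pytest

from goaelm.synthdata import ImageDatasetSpec, generate_synthetic_images


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture(scope="session")
def small_image_set(tmp_path_factory):
    """A tiny on-disk phantom set shared across feature/pipeline tests."""
    out = tmp_path_factory.mktemp("phantoms")
    spec = ImageDatasetSpec(
        n_images=24, blob_intensity_lift=0.45, noise_sd=0.02, seed=11
    )
    manifest = generate_synthetic_images(spec, out)
    return out, manifest, spec
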
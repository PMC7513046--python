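import numpy as np
import pytest

from nssfuse import FusionConfig, SynthSpec, fuse, make_multifocus_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def multifocus_256():
    """The reference multi-focus scenario: 256x256, blur sigma 3, seed 0."""
    spec = SynthSpec(size=(256, 256), blur_sigma=3.0, seed=0)
    a, b, gt, mask = make_multifocus_pair(spec)
    return {"spec": spec, "a": a, "b": b, "gt": gt, "mask": mask}


@pytest.fixture(scope="session")
def fused_256(multifocus_256):
    """NSS fusion of the reference multi-focus pair (computed once)."""
    cfg = FusionConfig(seed=0)
    return fuse(multifocus_256["a"], multifocus_256["b"], cfg)


@pytest.fixture(scope="session")
def multifocus_128():
    spec = SynthSpec(size=(128, 128), blur_sigma=3.0, seed=0)
    a, b, gt, mask = make_multifocus_pair(spec)
    return {"spec": spec, "a": a, "b": b, "gt": gt, "mask": mask}
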
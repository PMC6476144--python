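import numpy as np
import pytest

from nodedce.enhancement import compute_nde
from nodedce.image_io import RoiMask
from nodedce.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default noisy, motionless phantom: (series, truth)."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, textureless, motionless phantom: (series, truth, spec)."""
    spec = PhantomSpec(noise_sigma=0.0, texture_amp=0.0)
    series, truth = generate_phantom(spec)
    return series, truth, spec


@pytest.fixture(scope="session")
def clean_nde(clean_phantom):
    series, truth, _ = clean_phantom
    return compute_nde(
        series, RoiMask(truth.node_mask, "node"), RoiMask(truth.muscle_mask, "muscle")
    )


def truth_labels(truth, coords):
    """inner=True/outer=False per pixel, in NDECurveSet coordinate order."""
    return np.array([truth.inner_mask[r, c] for r, c in coords])
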
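import numpy as np
import pytest

from fusiondry.datasets import (
    CubeSpec,
    DryingCurveParams,
    DryingDesign,
    EnoseSpec,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_cube_spec():
    """Desk-scale cube geometry shared by the pipeline tests."""
    return CubeSpec(height=48, width=48)


@pytest.fixture(scope="session")
def noise_off_cube(small_cube_spec):
    """One noise-free cube at mid-drying moisture, with its ground truth."""
    from fusiondry.datasets import generate_cube

    mc = 0.45
    raw, white, black, mask = generate_cube(mc, small_cube_spec, rng=0, noise=False)
    return {"mc": mc, "raw": raw, "white": white, "black": black,
            "mask": mask, "spec": small_cube_spec}


@pytest.fixture(scope="session")
def small_dataset(small_cube_spec):
    """A 13-stage x 2-replicate noisy dataset (26 samples) for pipeline tests."""
    return generate_dataset(
        design=DryingDesign(replicates_per_stage=2),
        cube_spec=small_cube_spec,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_blocks(small_dataset):
    from fusiondry.fusion import extract_feature_blocks

    return extract_feature_blocks(small_dataset)
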
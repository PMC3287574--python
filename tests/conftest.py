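import numpy as np
import pytest
from hypothesis import settings

from mammoseg import PhantomSpec, compare_filters, generate_phantom, standard_suite

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# Printed confusion counts and the corresponding published 2-dp metric rows
# (hitting, missing, over_hitting, relative_hitting, relative_missing, kappa)
# for the eight reference cases.
REFERENCE_CASES = {
    "0046": ((4517, 635, 825), (0.85, 0.15, 0.12, 0.88, 0.16, 0.86)),
    "0051": ((3235, 370, 179), (0.95, 0.05, 0.11, 0.90, 0.05, 0.92)),
    "0069": ((2913, 1475, 140), (0.95, 0.05, 0.48, 0.66, 0.03, 0.78)),
    "0074": ((12912, 2611, 4654), (0.74, 0.26, 0.15, 0.83, 0.30, 0.78)),
    "0123": ((7419, 1452, 2566), (0.74, 0.26, 0.15, 0.84, 0.29, 0.79)),
    "0161": ((4339, 2050, 858), (0.83, 0.17, 0.39, 0.68, 0.13, 0.75)),
    "0226": ((18834, 890, 575), (0.97, 0.03, 0.05, 0.95, 0.03, 0.96)),
    "0274": ((1583, 704, 80), (0.95, 0.05, 0.42, 0.69, 0.03, 0.80)),
}


@pytest.fixture(scope="session")
def two_level_disk():
    """Noiseless, texture-free 64x64 disk phantom: an ideal two-level image."""
    spec = PhantomSpec(seed=3, height=64, width=64, radius=18.0, contrast=150.0,
                       softness=0.25, background_level=50.0,
                       texture_sigma=0.0, noise_sigma=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def standard_phantom():
    """First fixture of the standard suite (256x256, noisy, textured)."""
    return generate_phantom(standard_suite()[0])


@pytest.fixture(scope="session")
def filter_comparison_table():
    """Filter comparison over the full standard 20-phantom suite.

    Session-scoped: this is the expensive end-to-end computation shared by
    the pipeline-quality and filter-ordering checks.
    """
    return compare_filters(standard_suite())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
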
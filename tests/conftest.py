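"""Shared fixtures: small, fast phantoms exercised by most test modules."""

import numpy as np
import pytest

from lumenfill import PhantomSpec, RunConfig, generate_phantom


def small_spec(**overrides) -> PhantomSpec:
    """A reduced-scale phantom (outer R = 14 µm) that renders in ~0.1 s.

    Geometry scaled down from the default spheroid while keeping the
    lumen diameter (18 µm) well above the 6 µm cell alpha radius, so the
    cavity is not bridged; nucleus count follows the same Poisson-coverage
    packing argument (~50% shell occupancy).
    """
    base = dict(
        outer_radius_um=14.0,
        lumen_radius_um=9.0,
        nucleus_radius_um=2.5,
        shell_nucleus_count=90,
        stack_shape=(20, 80, 80),
        seed=0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture
def hollow_small():
    return generate_phantom(small_spec(seed=11))


@pytest.fixture
def filled_small():
    return generate_phantom(small_spec(seed=12, fill_fraction=1.0))


@pytest.fixture
def clean_small():
    """Noise-free, blur-free small phantom: mask recovery is near-exact."""
    return generate_phantom(small_spec(seed=13, psf_sigma_um=0.0, noise_sd=0.0))


@pytest.fixture
def run_config(tmp_path):
    return RunConfig(manifest="unused", out_dir=str(tmp_path / "run"))


@pytest.fixture
def rng():
    return np.random.default_rng(424242)
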
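"""Shared fixtures: phantoms are generated once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

from condylar import pipeline
from condylar.synthetic_phantom import (
    PhantomSpec,
    RemodelSpec,
    apply_remodeling,
    generate_phantom,
)

#: The remodelling prescription exercised end-to-end: a coronal rotation
#: mirroring the reference cohort's right-side mean, anterior apposition /
#: posterior resorption, and a 30 % density drop.
RECOVERY_REMODEL = RemodelSpec(
    axis_rotation_deg=6.9,
    intercondylar_delta_deg=-10.8,
    surface_offsets_mm={"anterior": 0.2, "posterior": -0.2},
    density_scale=0.7,
    hu_noise_sd=5.0,
)


@pytest.fixture(scope="session")
def phantom_t0_coarse():
    """T0 study + truth at 0.5 mm voxel pitch (cheap, reused widely)."""
    spec = PhantomSpec(voxel_spacing_mm=0.5, seed=11)
    study, truth = generate_phantom(spec)
    return spec, study, truth


@pytest.fixture(scope="session")
def phantom_pair_fine():
    """0.25 mm pre/post pair with the recovery prescription, fully measured."""
    spec = PhantomSpec(voxel_spacing_mm=0.25, seed=11)
    t0, truth = generate_phantom(spec)
    t1, truth = apply_remodeling(t0, truth, RECOVERY_REMODEL, spec)
    measured = pipeline.compare_pair(t0, t1)
    return spec, t0, t1, truth, measured


@pytest.fixture(scope="session")
def phantom_pair_noop():
    """0.5 mm pair with an all-zero remodel: every delta should vanish."""
    spec = PhantomSpec(voxel_spacing_mm=0.5, seed=23)
    t0, truth = generate_phantom(spec)
    t1, truth = apply_remodeling(t0, truth, RemodelSpec(), spec)
    measured = pipeline.compare_pair(t0, t1)
    return spec, truth, measured


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
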
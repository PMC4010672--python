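"""Shared fixtures: gradient scheme, canonical tensors, and one fitted cohort.

The session-scoped cohort is expensive (45 free-water fits), so every module
test that needs group-level maps shares it.
"""

import numpy as np
import pytest

import fwelim as fw
from fwelim.phantom import default_cohort_spec, default_phantom_spec, simulate_cohort
from fwelim.pipeline import fit_cohort

#: canonical healthy bundle tensor (mm^2/s)
D_TISSUE = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
MD_TISSUE = 0.7666666666666667e-3
FA_TISSUE = 0.7990271176834392


@pytest.fixture(scope="session")
def scheme30():
    """30 isotropically spread directions at b=1200 plus 3 b=0 volumes."""
    return fw.make_gradient_scheme(30, 1200.0, 3, seed=42)


@pytest.fixture(scope="session")
def atrophy_cohort(scheme30):
    """Atrophy-only 25-vs-20 cohort at the default study conditions."""
    subjects = simulate_cohort(default_phantom_spec(),
                               default_cohort_spec(seed=2025), scheme30)
    return subjects


@pytest.fixture(scope="session")
def atrophy_cohort_fits(atrophy_cohort):
    return fit_cohort(atrophy_cohort)


def single_voxel_dwi(scheme, f=1.0, tensor=None, s0=1000.0, noise_sigma=0.0,
                     seed=0):
    """One-voxel DWIVolume from the two-compartment forward model."""
    tensor = D_TISSUE if tensor is None else tensor
    tensors = np.asarray(tensor).reshape(1, 1, 1, 3, 3)
    fmap = np.full((1, 1, 1), float(f))
    return fw.simulate_signal(tensors, fmap, scheme, s0=s0,
                              noise_sigma=noise_sigma, seed=seed)
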
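"""Shared fixtures: small, fast systems used across the unit tests."""

import numpy as np
import pytest

from ghostmd.descriptors import SymmetryFunctionSet
from ghostmd.toy import (Dataset, ToyModelParams, build_box, toy_energy_forces)


@pytest.fixture(scope="session")
def tiny_params():
    """Toy parameters with a cutoff that fits an 8-molecule box (L ≈ 5.7 Å)."""
    return ToyModelParams(r_cut=2.8)


@pytest.fixture(scope="session")
def small_box(tiny_params):
    return build_box(8, density=1.3, seed=3, params=tiny_params)


@pytest.fixture(scope="session")
def jittered_box(small_box):
    box = small_box.copy()
    rng = np.random.default_rng(0)
    box.positions = box.positions + 0.06 * rng.standard_normal(box.positions.shape)
    return box


@pytest.fixture(scope="session")
def tiny_sfset():
    return SymmetryFunctionSet(r_cut=2.7, r_cut_angular=2.3)


@pytest.fixture(scope="session")
def tiny_dataset(small_box, tiny_params):
    """8 jittered labeled frames of the 8-molecule neat box."""
    rng = np.random.default_rng(1)
    samples = []
    for _ in range(8):
        cfg = small_box.copy()
        cfg.positions = cfg.positions + 0.05 * rng.standard_normal(cfg.positions.shape)
        samples.append(toy_energy_forces(cfg, tiny_params))
    return Dataset(samples, has_ghost=False, metadata=dict(n_molecules=8))
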
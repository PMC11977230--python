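"""Shared fixtures: expensive synthetic datasets built once per session."""

import numpy as np
import pytest

from coev import synth


@pytest.fixture(scope="session")
def big_gaussian_traj():
    """150-residue Gaussian chain, 20000 frames, one planted rho=0.5 pair."""
    spec = synth.GaussianTrajSpec(
        n_residues=150, n_frames=20000, sigma=0.5,
        rho={(50, 100): 0.5}, seed=11,
    )
    traj, truth = synth.make_gaussian_trajectory(spec)
    return traj, truth


@pytest.fixture(scope="session")
def landscape_traj_single():
    """Element-distance trajectory with one planted mode at (11, 13) A."""
    spec = synth.GaussianTrajSpec(
        n_frames=6000, landscape_modes=[(11.0, 13.0, 1.0, 0.3)], seed=12,
    )
    return synth.make_gaussian_trajectory(spec)


@pytest.fixture(scope="session")
def landscape_traj_bimodal():
    """50/50 mixture of two well-separated element-distance modes."""
    spec = synth.GaussianTrajSpec(
        n_frames=6000,
        landscape_modes=[(10.0, 9.0, 0.5, 0.25), (14.0, 13.0, 0.5, 0.25)],
        seed=13,
    )
    return synth.make_gaussian_trajectory(spec)


@pytest.fixture(scope="session")
def planted_msa_small():
    """Planted-coupling alignment small enough for per-test SCA runs."""
    spec = synth.CoupledMsaSpec(
        n_seq=600, L=60, planted=(5, 15, 25, 35, 45), p=0.9, seed=7,
    )
    return synth.make_coupled_msa(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
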
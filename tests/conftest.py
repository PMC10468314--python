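import numpy as np
import pytest

from asvlmm import (
    GenotypeFactor,
    SimDesign,
    SimTruth,
    build_kasv,
    simulate_focal_locus,
    simulate_genotypes,
    simulate_trait,
)


@pytest.fixture(scope="session")
def small_markers():
    """Small outbred marker panel shared by kernel and model tests."""
    return simulate_genotypes(n=60, m=150, H_target=0.38, ld_rho=0.8, seed=20240)


@pytest.fixture(scope="session")
def small_focal(small_markers):
    return simulate_focal_locus(
        small_markers.n, "outbred", seed=77, entries=small_markers.entries
    )


@pytest.fixture(scope="session")
def small_kasv(small_markers):
    return build_kasv(small_markers)


@pytest.fixture(scope="session")
def small_met():
    """A small balanced multi-environment trial with known ground truth."""
    gen = np.random.default_rng(555)
    markers = simulate_genotypes(n=40, m=100, H_target=0.38, ld_rho=0.8, rng=gen)
    focal = simulate_focal_locus(40, "outbred", rng=gen, entries=markers.entries)
    design = SimDesign(
        n_entries=40, m_loci=100, reps=2, n_env=3, block_effects=True
    )
    truth = SimTruth(
        targets={"m": 40.0, "g": 66.0, "gR": 50.0, "ge": 90.0, "eps": 40.0, "block": 20.0},
        design=design,
        seed=555,
    )
    plot_df, truth = simulate_trait(markers, focal, truth, rng=gen)
    return markers, focal, build_kasv(markers), plot_df, truth
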
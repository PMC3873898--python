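"""Shared fixtures: all structural inputs are generated, never stored."""

import pytest

from unfoldscope import synthetic_data as sd


@pytest.fixture(scope="session")
def helix12():
    """Ideal 12-residue α-helix."""
    return sd.build_backbone(12, "H" * 12)


@pytest.fixture(scope="session")
def strand12():
    """Fully extended 12-residue chain (no backbone H-bonds)."""
    return sd.make_extended_strand(12)


@pytest.fixture(scope="session")
def coil12():
    """Seeded 12-residue random coil."""
    return sd.build_backbone(12, "C" * 12, seed=3)


@pytest.fixture(scope="session")
def hairpin():
    """Idealized two-strand antiparallel hairpin (8 residues per strand)."""
    return sd.make_antiparallel_hairpin(8)


@pytest.fixture(scope="session")
def native_globin():
    """Compact 153-residue, eight-helix globin mimic with heme."""
    return sd.make_native_globin(seed=0)


@pytest.fixture(scope="session")
def unfolding():
    """200-frame exponential-unfolding trajectory (λ = 0.2 ns⁻¹, t_loss = 3.7 ns)."""
    return sd.make_unfolding_trajectory(sd.UnfoldingConfig(seed=42))


@pytest.fixture(scope="session")
def unfolding_ss(unfolding):
    """Secondary-structure time series of the unfolding trajectory."""
    from unfoldscope.secondary_structure import ss_timeseries

    traj, _ = unfolding
    return ss_timeseries(traj)


@pytest.fixture(scope="session")
def phase_traj():
    """Three-plateau (native / intermediate / unfolded) trajectory."""
    return sd.make_phase_trajectory(seed=11, frames_per_phase=30)
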
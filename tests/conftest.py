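import pytest

import classinet as cn


@pytest.fixture(scope="session")
def hex_truth():
    """Unperturbed, axis-aligned honeycomb lattice with its ideal network."""
    cfg = cn.SimConfig(
        pattern="2d_hex", jitter_sigma=0.0, miss_rate=0.0, rotation_deg=0.0,
        seed=2, extent=(4000.0, 4000.0),
    )
    clusters, truth = cn.simulate_pattern(cfg)
    return cfg, clusters, truth


@pytest.fixture(scope="session")
def oned_composite():
    """1D-periodic island on a density-matched CSR background (6.1 µm)."""
    ext = (6144.0, 6144.0)
    island = cn.SimConfig(pattern="1d_periodic", seed=5, extent=ext)
    background = cn.SimConfig(pattern="csr", seed=6, extent=ext)
    clusters, truth = cn.make_composite(island, background, boundary_seed=2)
    return clusters, truth, ext


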
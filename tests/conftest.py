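import numpy as np
import pytest

from edgesync import RunConfig, SimSpec, run_pipeline, simulate_group


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_sim():
    """One group simulated under the default study conditions."""
    return simulate_group(SimSpec(seed=7))


@pytest.fixture(scope="session")
def default_result(default_sim):
    """Full pipeline run on the default simulation (shared across tests)."""
    sim = default_sim
    cfg = RunConfig(seed=7)
    manifest = {
        "movie": sim.movie_scans,
        "rest": sim.rest_scans,
        "boundaries": sim.boundary_frames,
        "centroids": sim.centroids,
    }
    return run_pipeline(cfg, manifest)


@pytest.fixture(scope="session")
def small_sim():
    """A lighter group for pipeline plumbing tests."""
    spec = SimSpec(
        n_subjects=5, n_nodes=24, n_systems=4, n_frames=200,
        boundary_frames=(40, 120), movie_event_frames=(80,),
        n_rest_scans=2, seed=3,
    )
    return simulate_group(spec)
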
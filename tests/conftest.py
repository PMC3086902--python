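import numpy as np
import pytest

from szaggr import aggregates, core_io, synthetic_data


@pytest.fixture(scope="session")
def antiparallel_dimer():
    """Ideal in-register antiparallel two-strand trajectory (chains A, B)."""
    return synthetic_data.build_ideal_dimer_trajectory("antiparallel")


@pytest.fixture(scope="session")
def parallel_dimer():
    return synthetic_data.build_ideal_dimer_trajectory("parallel")


@pytest.fixture(scope="session")
def reference_dimers():
    return {
        "parallel": core_io.build_reference_dimer("parallel_in_register"),
        "antiparallel": core_io.build_reference_dimer("antiparallel_in_register"),
    }


@pytest.fixture(scope="session")
def sim_small():
    """Short aggregation run used by structural-invariant tests."""
    cfg = synthetic_data.SimConfig(n_frames=300, seed=11)
    traj, truth = synthetic_data.simulate_aggregation(cfg)
    return cfg, traj, truth


@pytest.fixture(scope="session")
def sim_small_partitions(sim_small):
    _, traj, _ = sim_small
    return [aggregates.general_aggregates(
        aggregates.heavy_atom_contacts(traj.frame(f)))
        for f in range(traj.n_frames)]


@pytest.fixture(scope="session")
def labeled_ensemble():
    """800 labeled dimer records around the four default templates."""
    coords, labels, names = synthetic_data.make_dimer_ensemble(
        n_per_template=200, sigma=0.01, seed=5)
    return coords, labels, names


def single_atom_chains(distances, box=None):
    """Topology/frame with one heavy atom per chain at given x positions."""
    n = len(distances)
    top = core_io.Topology([chr(65 + i) for i in range(n)],
                           np.arange(n), np.ones(n, int),
                           np.array(["ALA"] * n), np.array(["CB"] * n),
                           np.array(["C"] * n))
    coords = np.zeros((n, 3))
    coords[:, 0] = distances
    b = None if box is None else np.full(3, float(box))
    return core_io.Frame(0.0, b, coords, top)
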
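import numpy as np
import pytest

import switchscan as ss

CORPUS_SEED = 7


@pytest.fixture(scope="session")
def corpus600():
    """600-item balanced synthetic corpus (200 per class), clear margins."""
    dataset, truth = ss.gen_labeled_corpus(n_per_class=200, seed=CORPUS_SEED)
    return dataset, truth


@pytest.fixture(scope="session")
def toy_system(tmp_path_factory):
    """Toy 3-residue system: one SS, one US, one static residue; two DCDs."""
    specs = [
        ss.AngleDynamicsSpec("ss", schedule=(300,), n_frames=1000, seed=11),
        ss.AngleDynamicsSpec("us", switch_rate=0.1, n_frames=1000, seed=12),
        None,
    ]
    out = tmp_path_factory.mktemp("toy")
    return ss.gen_toy_trajectory(specs, out, n_trajectories=2)


@pytest.fixture(scope="session")
def toy_trajectories(toy_system):
    return ss.TrajectorySet.from_files(toy_system.pdb_path, toy_system.trajectory_paths)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
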
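import numpy as np
import pytest

from clusso.clustering import cluster_pooled, clustering_accuracy
from clusso.data_io import OutcomeVector, TubuleTable
from clusso.simulation import SimulationConfig, generate_dataset


@pytest.fixture
def toy_tubules() -> TubuleTable:
    """Three subjects, q=2, hand-sized for exact arithmetic."""
    return TubuleTable(
        subject_ids=np.array(["A", "A", "A", "B", "B", "C", "C"]),
        object_ids=np.array([1, 2, 3, 1, 2, 1, 2]),
        features=np.array(
            [[1.0, 3.0], [3.0, 5.0], [10.0, 20.0],
             [2.0, 2.0], [4.0, 6.0],
             [0.0, 1.0], [8.0, 9.0]]
        ),
        feature_names=["f1", "f2"],
    )


@pytest.fixture
def toy_outcomes() -> OutcomeVector:
    return OutcomeVector(np.array(["A", "B", "C"]), np.array([1.0, 2.0, 3.0]))


def _mean_accuracy(sigma2_R: float, reps: int, base_seed: int) -> float:
    accs = []
    for r in range(reps):
        cfg = SimulationConfig(
            n=500, q=10, s_beta=0.8, sigma2_R=sigma2_R, seed=base_seed + r
        )
        tubules, _, _, true_labels = generate_dataset(cfg)
        assignment = cluster_pooled(tubules, G=2, algorithm="gmm", seed=cfg.seed)
        accs.append(
            clustering_accuracy(assignment.labels, true_labels, tubules.subject_ids)
        )
    return float(np.mean(accs))


@pytest.fixture(scope="session")
def gmm_accuracy_by_noise() -> dict[float, float]:
    """Mean-of-means GMM clustering accuracy on the two-cluster generator.

    20 repetitions at n=500, q=10 for each resampling variance; shared across
    the clustering monotonicity test and the accuracy acceptance checks.
    """
    return {s2: _mean_accuracy(s2, reps=20, base_seed=20_000) for s2 in (1.0, 21.0, 46.0)}
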
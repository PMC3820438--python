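import numpy as np
import pytest

from pi1bench import ExpressionMatrix, ScenarioConfig, simulate_dataset, synth_parameter_table


@pytest.fixture
def tiny_matrix():
    """3 genes x 6 samples (3 vs 3), hand-checkable values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 3.0, 4.0, 5.0],
            [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
            [0.0, 1.0, 2.0, 4.0, 5.0, 6.0],
        ]
    )
    return ExpressionMatrix(
        values=values,
        gene_ids=np.array(["g1", "g2", "g3"]),
        group=np.array(["a", "a", "a", "b", "b", "b"]),
    )


def make_dataset(G=500, pi1=0.1, n1=8, n2=6, sim_type="EV", seed=0):
    params = synth_parameter_table(G, pi1, seed=seed)
    cfg = ScenarioConfig(sim_type=sim_type, n1=n1, n2=n2, pi1=pi1, G=G)
    return simulate_dataset(params, cfg, seed=seed + 1)


@pytest.fixture
def small_dataset():
    return make_dataset()
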
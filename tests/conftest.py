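import numpy as np
import pytest

import txclust as tc


@pytest.fixture(scope="session")
def surrogate_pair():
    """A 400-gene surrogate matrix with its generating NB truth."""
    return tc.generate_surrogate_panel(
        tc.SurrogateProfile(n_genes=400, n_samples=55, seed=42)
    )


@pytest.fixture(scope="session")
def panel_params(surrogate_pair):
    """NB MLEs for the surrogate's top-100-MAD panel."""
    matrix, _ = surrogate_pair
    panel = tc.select_top_mad(matrix, 100)
    return tc.estimate_panel_params(matrix, panel)


@pytest.fixture(scope="session")
def sim_batch_k3(panel_params):
    """Three TE / K=3 simulated datasets."""
    design = tc.build_design("TE", 3, n_datasets=3, base_seed=7)
    return design, tc.simulate_batch(panel_params, design)


@pytest.fixture
def small_matrix():
    counts = np.array(
        [
            [0, 1, 2, 3],
            [5, 5, 5, 5],
            [10, 0, 30, 2],
            [100, 200, 150, 120],
            [7, 8, 9, 6],
        ]
    )
    return tc.CountMatrix(
        counts,
        gene_ids=("gA", "gB", "gC", "gD", "gE"),
        sample_ids=("s1", "s2", "s3", "s4"),
    )
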
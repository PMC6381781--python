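import numpy as np
import pandas as pd
import pytest

from qcoexp import (
    BaitSet,
    DiscretizationParams,
    ExpressionMatrix,
    GeneAnnotation,
    ModuleSpec,
    ScreenParams,
    SyntheticSpec,
    discretize_matrix,
    generate_matrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 conditions with simple integer values."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.0, 5.0, 5.0, 5.0]],
            index=["g1", "g2", "g3"],
            columns=["c1", "c2", "c3", "c4"],
        )
    )


@pytest.fixture
def planted():
    """A small planted-module matrix: 2 baits x 2 partners, zero noise.

    With no noise the baseline is exactly tied, so discretization marks
    precisely the planted condition subsets and the screen must recover
    every planted pair with BF equal to the subset size.
    """
    spec = SyntheticSpec(
        n_genes=40,
        n_conditions=40,
        modules=(
            ModuleSpec("B01", ("B01P1", "B01P2"), condition_subset=0.25, effect_size=5.0),
            ModuleSpec("B02", ("B02P1", "B02P2"), condition_subset=0.25, effect_size=5.0),
        ),
        noise_sd=0.0,
        rng_seed=11,
    )
    matrix, truth = generate_matrix(spec)
    d = discretize_matrix(matrix, DiscretizationParams(q=0.25))
    return matrix, d, truth


@pytest.fixture
def annotations():
    return {
        "B01P1": GeneAnnotation("B01P1", tf_family="MYB", species="Pv"),
        "B01P2": GeneAnnotation("B01P2", tf_family="NAC", species="Pv"),
        "B02P1": GeneAnnotation("B02P1", tf_family="MYB", species="Pv"),
        "G0001": GeneAnnotation("G0001", tf_family=None, species="Pv"),
    }


@pytest.fixture
def fast_params():
    return ScreenParams(min_bf=5, alpha=0.05, n_permutations=200, rng_seed=3)


@pytest.fixture
def baits2():
    return BaitSet(("B01", "B02"), label="test-baits")
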
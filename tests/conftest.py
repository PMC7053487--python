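import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from atranet.io import DIFF, UNDIFF, ExpressionMatrix
from atranet.simulate import (
    PlantedModel,
    generate_expression_dataset,
    generate_genome_fixture,
    generate_homolog_fixture,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def toy_matrix(values, n_und, n_dif, cell_line="toy"):
    """Small probe x sample matrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    probes = [f"p{i + 1}" for i in range(values.shape[0])]
    samples = [f"s{i + 1}" for i in range(values.shape[1])]
    condition = pd.Series(
        [UNDIFF] * n_und + [DIFF] * n_dif, index=samples
    )
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=probes, columns=samples),
        condition=condition,
        cell_line=cell_line,
    )


@pytest.fixture(scope="session")
def small_model():
    """A small but informative planted dataset shared across tests."""
    model = PlantedModel(
        n_tfs=6, n_genes=40, samples_per_condition=30, seed=7
    )
    matrices, model = generate_expression_dataset(model, n_cell_lines=3)
    return matrices, model


@pytest.fixture(scope="session")
def genome_fixture():
    return generate_genome_fixture(seed=3)


@pytest.fixture(scope="session")
def homolog_fixture():
    return generate_homolog_fixture(seed=5)
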
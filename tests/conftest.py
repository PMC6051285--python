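import numpy as np
import pandas as pd
import pytest

from sensmark import (
    DataType,
    GenomicsMatrix,
    GroupLabels,
    SimulationConfig,
    generate_cell_line_panel,
    generate_clinical_cohort,
    label_samples_by_ic50,
)


def make_matrix(values, data_type=DataType.EXPRESSION, genes=None, samples=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return GenomicsMatrix(data_type, pd.DataFrame(values, index=genes, columns=samples))


def make_labels(label_list, samples=None):
    samples = samples or [f"s{i}" for i in range(len(label_list))]
    return GroupLabels(pd.Series(list(label_list), index=samples, name="label"))


@pytest.fixture
def labels_2v2():
    return make_labels(["Sensitive", "Sensitive", "Resistant", "Resistant"])


@pytest.fixture
def labels_3v3():
    return make_labels(
        ["Sensitive", "Sensitive", "Sensitive", "Resistant", "Resistant", "Resistant"]
    )


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def panel(sim_config):
    expr, cn, mut, sens = generate_cell_line_panel(sim_config)
    return {
        "expression": expr,
        "copy_number": cn,
        "mutation": mut,
        "sensitivity": sens,
        "labels": label_samples_by_ic50(sens),
    }


@pytest.fixture(scope="session")
def cohort(sim_config):
    matrices, clinical, latent = generate_clinical_cohort(sim_config)
    return {"matrices": matrices, "clinical": clinical, "latent": latent}
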
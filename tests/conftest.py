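import numpy as np
import pandas as pd
import pytest

from stratomic.datatypes import ClinicalTable, ProteinMatrix
from stratomic.synthetic import PanelFeature, SyntheticConfig, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_protein_matrix(values, state="log2", sample_prefix="S", protein_prefix="P"):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"{sample_prefix}{i}" for i in range(values.shape[0])],
        columns=[f"{protein_prefix}{j}" for j in range(values.shape[1])],
    )
    return ProteinMatrix(df, state=state)


def make_clinical(values, columns=None):
    values = np.asarray(values, dtype=float)
    cols = columns or [f"F{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"S{i}" for i in range(values.shape[0])], columns=cols)
    return ClinicalTable(df)


@pytest.fixture(scope="session")
def tiny_signal_cohort():
    """60 samples, 3 groups, 2 strongly informative proteins, light missingness."""
    config = SyntheticConfig(
        group_sizes={"CTRL": 20, "DLP": 20, "AT": 20},
        n_proteins=20,
        n_clinical=5,
        panel_spec=(
            PanelFeature("PROT0001", "AT", 3.0, "up"),
            PanelFeature("PROT0002", "DLP", 3.0, "up"),
        ),
        mcar_rate=0.02,
        clinical_missing_rate=0.05,
        seed=7,
    )
    return generate_cohort(config)
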
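import dataclasses

import numpy as np
import pandas as pd
import pytest

from mirpanel.cascade import label_samples
from mirpanel.cohort import CohortConfig, simulate_cohort
from mirpanel.matrix import LOG2, SignalMatrix, sheet_index
from mirpanel.preprocess import preprocess_chain


#: Scaled-down cohort used by most tests: keeps the design shape
#: (chronological + paired + control arms, recurrence cases) while staying
#: fast enough for seed ensembles.
SMALL = CohortConfig(
    n_crc=30, n_crc_chronological=24, n_normal=24, n_recurrence=6,
    n_probes=160, n_true_markers=8, n_negative_controls=16,
    seed=11,
)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return SMALL


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    matrix, sheet, truth = small_cohort
    normalized, calls = preprocess_chain(matrix,
                                         batches=sheet_index(sheet)["batch"])
    return normalized, sheet, truth, calls


@pytest.fixture(scope="session")
def small_labeling(small_cohort):
    _, sheet, _ = small_cohort
    return label_samples(sheet)


def make_log2_matrix(values: np.ndarray, probe_prefix: str = "g",
                     sample_prefix: str = "s") -> SignalMatrix:
    """Wrap a plain array as a log2 SignalMatrix (no negative controls)."""
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(values,
                      index=[f"{probe_prefix}{i}" for i in range(values.shape[0])],
                      columns=[f"{sample_prefix}{j}" for j in range(values.shape[1])])
    meta = pd.DataFrame({"is_negative_control": False}, index=df.index)
    return SignalMatrix(values=df, probe_meta=meta, scale=LOG2)


def scaled(config: CohortConfig = SMALL, **overrides) -> CohortConfig:
    return dataclasses.replace(config, **overrides)
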
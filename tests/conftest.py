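import numpy as np
import pandas as pd
import pytest

from peptistage import CohortConfig, MSMap, MarkerTable, generate_cohort, simulate_marker_table


@pytest.fixture(scope="session")
def small_cohort():
    """A 6+6 cohort with 10 planted markers, used across preprocessing tests."""
    config = CohortConfig(n_early=6, n_late=6, n_peaks=300, n_diff=10,
                          n_landmarks=5, seed=3)
    maps, manifest, truth = generate_cohort(config)
    return config, maps, manifest, truth


@pytest.fixture(scope="session")
def confirmation_table():
    """A 20+19 marker table from the cohort intensity model: 25 null markers
    followed by 5 planted two-fold markers."""
    config = CohortConfig(n_peaks=25, n_diff=5, seed=11)
    return simulate_marker_table(config)


def toy_table(values: np.ndarray, labels: list[str]) -> MarkerTable:
    """Hand-built MarkerTable: values is samples x markers."""
    values = np.asarray(values, dtype=float)
    n_samples, n_markers = values.shape
    serials = list(range(1, n_markers + 1))
    ids = [f"T{i}" for i in range(n_samples)]
    markers = pd.DataFrame({
        "serial": serials,
        "mz": 500.0 + 10.0 * np.arange(n_markers),
        "z": 1,
        "rt": 100.0 + 50.0 * np.arange(n_markers),
    })
    return MarkerTable(
        markers,
        pd.DataFrame(values, index=ids, columns=serials),
        pd.Series(labels, index=ids),
        pd.Series(["B1"] * n_samples, index=ids),
    )


@pytest.fixture()
def make_toy_table():
    return toy_table
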
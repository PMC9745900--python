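import numpy as np
import pandas as pd
import pytest

from mmscreen.doseresponse import DoseResponseFit
from mmscreen.simulate import (
    ScreenSimConfig,
    simulate_plate,
    simulate_variant_table,
)


def constant_fit(level: float) -> DoseResponseFit:
    """A degenerate fit whose predicted viability is constant."""
    return DoseResponseFit(
        model="LL4", b=0.0, c=level, d=level, e=100.0, converged=True,
        rss=0.0, n_points=5, degenerate=True,
    )


@pytest.fixture(scope="session")
def five_doses():
    return np.array([1.0, 10.0, 100.0, 1000.0, 10000.0])


@pytest.fixture()
def small_screen_config():
    cell_lines = ["A", "B"]
    drugs = ["d1", "d2", "d3"]
    params = {
        (cl, dr): (1.5, 0.0, 100.0, 10.0 ** (1 + i))
        for cl in cell_lines
        for i, dr in enumerate(drugs)
    }
    return ScreenSimConfig(
        cell_lines=cell_lines,
        drugs=drugs,
        true_params=params,
        noise_sd=0.0,
        replicate_count=2,
        seed=7,
    )


@pytest.fixture()
def small_raw_screen(small_screen_config):
    return simulate_plate(small_screen_config)


@pytest.fixture(scope="session")
def variant_fixture() -> pd.DataFrame:
    return simulate_variant_table(n_variants=12, seed=0)


@pytest.fixture(scope="session")
def dss_matrix_small() -> pd.DataFrame:
    """A small deterministic score matrix with clear drug co-response blocks."""
    rng = np.random.default_rng(11)
    base = rng.uniform(10, 70, size=(6, 8))
    base[1] = base[0] + rng.normal(0, 1, 8)  # drugs 0/1 strongly correlated
    base[3] = base[2] + rng.normal(0, 1, 8)
    mat = pd.DataFrame(
        base,
        index=[f"drug{i}" for i in range(6)],
        columns=[f"cl{i}" for i in range(8)],
    )
    mat.index.name = "drug"
    mat.columns.name = "cell_line"
    return mat
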
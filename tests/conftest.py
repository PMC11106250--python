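import hypothesis
import numpy as np
import pandas as pd
import pytest

from mrmediate.datasets import load_ocn_instruments
from mrmediate.simulate import SimulationConfig, simulate_study
from mrmediate.sumstats import SummaryStatsTable, _FIELDS

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def ocn_all():
    return load_ocn_instruments()


@pytest.fixture(scope="session")
def ocn_eldjarn():
    return load_ocn_instruments("ELDJARN")


@pytest.fixture()
def small_study():
    """A no-pleiotropy exposure/outcome study with 10 strong instruments."""
    return simulate_study(SimulationConfig(j_instruments=10, seed=42))


def make_table(trait, trait_type, rows):
    """Build a SummaryStatsTable from (snp, chr, bp, ea, oa, eaf, beta, se, p, n)."""
    frame = pd.DataFrame(rows, columns=_FIELDS)
    return SummaryStatsTable(trait, trait_type, frame)


@pytest.fixture()
def pairs_frame():
    """Harmonized-pair frame factory for estimator tests."""

    def build(theta_j, se_j, bx=None, sx=1e-9):
        theta_j = np.asarray(theta_j, float)
        se_j = np.broadcast_to(np.asarray(se_j, float), theta_j.shape)
        bx = np.ones_like(theta_j) if bx is None else np.asarray(bx, float)
        return pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(len(theta_j))],
            "beta_exposure": bx,
            "se_exposure": np.broadcast_to(np.asarray(sx, float), theta_j.shape),
            "beta_outcome": theta_j * bx,
            "se_outcome": se_j * np.abs(bx),
        })

    return build
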
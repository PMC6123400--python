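import pandas as pd
import pytest

from spermseq import qc
from spermseq.simulate import (
    SimulationSpec,
    simulate_dataset,
    simulate_psi_table,
)


@pytest.fixture(scope="session")
def default_sim():
    """One full-size simulated dataset shared across tests (default spec)."""
    spec = SimulationSpec(seed=11)
    cm, meta, ann, truth = simulate_dataset(spec)
    return spec, cm, meta, ann, truth


@pytest.fixture(scope="session")
def default_log_matrix(default_sim):
    _spec, cm, _meta, _ann, _truth = default_sim
    return qc.log_expr(qc.tpm(cm))


@pytest.fixture(scope="session")
def deep_two_stage_sim():
    """Two stages at default depth with many cells, for power-hungry checks."""
    spec = SimulationSpec(
        stages=("Z", "eP"),
        cells_per_stage=400,
        n_autosomal=4000,
        seed=12,
    )
    cm, meta, ann, truth = simulate_dataset(spec)
    return spec, cm, meta, ann, truth


@pytest.fixture(scope="session")
def psi_sim():
    spec = SimulationSpec(seed=13)
    table, truth = simulate_psi_table(spec)
    return spec, table, truth


@pytest.fixture()
def stages_series():
    def _of(meta: pd.DataFrame) -> pd.Series:
        return meta.set_index("cell_id")["stage"]

    return _of
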
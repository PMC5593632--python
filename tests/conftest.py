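import numpy as np
import pytest

from specbind import (
    QuenchSimConfig,
    load_qsar_table,
    simulate_quench_titration,
)


@pytest.fixture(scope="session")
def noiseless_sv_series():
    """Noiseless nine-point Stern-Volmer titration, Ksv = 22.84e6 L/mol."""
    return simulate_quench_titration(QuenchSimConfig(Ksv_true=22.84e6, seed=0))


@pytest.fixture(scope="session")
def noiseless_binding_series():
    """Noiseless titration obeying the double-log isotherm, K=22.47e6, n=1.02."""
    cfg = QuenchSimConfig(K_true=22.47e6, n_true=1.02, law="double_log", seed=0)
    return simulate_quench_titration(cfg)


@pytest.fixture(scope="session")
def activity_table():
    """Packaged 47-train / 14-test / 1-query inhibitor activity table."""
    return load_qsar_table()
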
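import pytest

from nglycopipe import default_design
from nglycopipe.synthetic import TruthConfig, simulate_glyco_experiment


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def sim(design):
    """One moderate synthetic experiment shared by read-only tests."""
    cfg = TruthConfig(n_proteins=80, seed=11)
    table, matrix, truth = simulate_glyco_experiment(design, cfg)
    return {"cfg": cfg, "table": table, "matrix": matrix, "truth": truth}
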
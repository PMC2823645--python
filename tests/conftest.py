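import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rcqge.simulate import ExpressionScenario, LadderDesign, simulate_expression

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_design() -> LadderDesign:
    return LadderDesign()


@pytest.fixture(scope="session")
def two_gene_scenario() -> ExpressionScenario:
    """One 2-fold up-regulated gene plus the housekeeping reference."""
    return ExpressionScenario(
        true_log10_fc={"GENE": np.log10(2.0), "HPRT": 0.0},
        baseline_log10_conc={"GENE": -15.0, "HPRT": -16.0},
        housekeeping="HPRT",
        n_per_group=6,
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_table(two_gene_scenario, default_design) -> pd.DataFrame:
    return simulate_expression(two_gene_scenario, default_design, seed=7)
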
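import numpy as np
import pandas as pd
import pytest

from metscreen import nca, synthetic_data as sd
from metscreen.model_io import ConnectivityMatrix, GLOBAL_REGULATOR_ID


@pytest.fixture(scope="session")
def small_scenario():
    """Identifiable 60-gene / 6-regulator noiseless scenario."""
    return sd.SyntheticScenario(
        n_genes=60,
        n_regulators=6,
        n_metabolites=8,
        noise_sd=0.0,
        metabolite_noise_cv=0.0,
        # identical grids so planted Hill parameters survive the
        # metabolome-transcriptome pairing without resampling error
        n_metabolome_timepoints=29,
        two_component_regulators=(),
        seed=1,
    )


@pytest.fixture(scope="session")
def small_bundle(small_scenario, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return sd.simulate_bundle(small_scenario, out), out


@pytest.fixture(scope="session")
def small_truth_parts(small_scenario):
    net = sd.generate_regulatory_network(small_scenario)
    act = sd.generate_tf_activities(small_scenario)
    expr = sd.generate_expression(act, net, small_scenario)
    return net, act, expr


@pytest.fixture(scope="session")
def small_ensemble(small_scenario, small_truth_parts):
    """Inferred activities on the noiseless small scenario (20 restarts)."""
    net, _, expr = small_truth_parts
    return nca.run_nca_ensemble(
        expr, net, nca.NcaSettings(n_restarts=20, seed=5)
    )


def diagonal_connectivity(n: int = 4, with_global: bool = False
                          ) -> ConnectivityMatrix:
    """n regulators each exclusively targeting one gene."""
    genes = [f"g{i}" for i in range(n)]
    regs = [f"r{i}" for i in range(n)]
    weights = pd.DataFrame(np.eye(n), index=regs, columns=genes)
    if with_global:
        weights.loc[GLOBAL_REGULATOR_ID] = 1.0
    return ConnectivityMatrix(weights)
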
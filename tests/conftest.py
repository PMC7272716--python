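import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lncnet import coexpression, datasets, simulate
from lncnet.io import ExpressionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hub_network() -> coexpression.CoexpressionNetwork:
    """The published six-hub edge list wrapped as a network."""
    return coexpression.CoexpressionNetwork.from_edge_list(datasets.hub_edge_table())


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 6 samples, handwritten values, 3-vs-3 design."""
    values = pd.DataFrame(
        {
            "case_1": [7.1, 3.9, 5.0],
            "case_2": [7.0, 4.1, 5.2],
            "case_3": [6.9, 4.0, 4.8],
            "control_1": [4.0, 4.0, 5.1],
            "control_2": [4.1, 3.9, 4.9],
            "control_3": [3.9, 4.1, 5.0],
        },
        index=["LNC_A", "MRNA_B", "MRNA_C"],
    )
    design = pd.Series(
        ["case"] * 3 + ["control"] * 3, index=values.columns, name="group"
    )
    biotype = pd.Series(["lncRNA", "mRNA", "mRNA"], index=values.index, name="biotype")
    return ExpressionMatrix(values=values, design=design, biotype=biotype)


@pytest.fixture
def hub_sim() -> tuple[ExpressionMatrix, simulate.GroundTruth]:
    """One planted-hub simulation at low noise."""
    cfg = simulate.SimulationConfig(
        n_genes=60,
        frac_lncrna=0.3,
        planted_hubs=(simulate.PlantedHub(size=8, target_r=0.999),),
        noise_sd=0.25,
        seed=7,
    )
    return simulate.generate_expression(cfg)


@pytest.fixture
def null_cohort() -> pd.DataFrame:
    rng = np.random.default_rng(11)
    n = 80
    return pd.DataFrame(
        {
            "sample": [f"p{i}" for i in range(n)],
            "time": rng.exponential(400.0, n) + 30.0,
            "event": rng.binomial(1, 0.7, n),
            "expression": rng.lognormal(0, 0.5, n),
            "er": rng.binomial(1, 0.5, n),
        }
    )
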
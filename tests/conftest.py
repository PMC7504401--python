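import pandas as pd
import pytest

from beconcord.diffexpr import ExpressionDataset
from beconcord.io import packaged_evidence, packaged_profile
from beconcord.simulate import CtSimSpec, ExpressionSimSpec, simulate_ct, simulate_expression


@pytest.fixture(scope="session")
def evidence():
    """The packaged three-dataset selection evidence table."""
    return packaged_evidence()


@pytest.fixture(scope="session")
def profile():
    """The packaged cross-system direction-profile fixture."""
    return packaged_profile()


@pytest.fixture
def tiny_dataset():
    """Hand-written 3-probe, 3+3-sample dataset with known group means."""
    values = pd.DataFrame(
        {
            "n1": [3.0, 1.0, 5.0],
            "n2": [3.0, 2.0, 5.5],
            "n3": [3.0, 3.0, 4.5],
            "b1": [5.0, 1.5, 5.2],
            "b2": [5.0, 2.5, 5.7],
            "b3": [5.0, 3.5, 4.1],
        },
        index=["pA", "pB", "pC"],
    )
    groups = pd.Series(
        ["normal"] * 3 + ["BE"] * 3, index=values.columns, name="group"
    )
    symbols = pd.Series(["GA", "GB", "GC"], index=values.index, name="gene_symbol")
    return ExpressionDataset(values=values, gene_symbols=symbols, groups=groups)


@pytest.fixture(scope="session")
def sim_expression():
    spec = ExpressionSimSpec(
        n_genes=500,
        n_per_group=7,
        true_logfc=[0.0] * 450 + [3.0] * 25 + [-3.0] * 25,
        d0=4.0,
        s0_sq=0.05,
        seed=20,
    )
    return simulate_expression(spec)


@pytest.fixture(scope="session")
def noiseless_ct():
    spec = CtSimSpec(
        genes=["ACTB", "GAPDH", "G_UP", "G_NC", "G_DOWN", "G_NA"],
        conditions=["control", "treated"],
        true_fold={
            "G_UP": {"treated": 4.0},
            "G_DOWN": {"treated": 0.25},
            "G_NC": {"treated": 1.0},
        },
        noise_sd=0.0,
        n_replicates=3,
        n_samples=4,
        na_genes=["G_NA"],
        seed=7,
    )
    return simulate_ct(spec)
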
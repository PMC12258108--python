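import numpy as np
import pandas as pd
import pytest

from prognet import ExpressionMatrix, PhenotypeTable, SimConfig, simulate_dataset


@pytest.fixture
def tiny_expr():
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [0.5, 0.5, 1.5, 1.5]],
            index=["A", "B", "C"],
            columns=["s1", "s2", "s3", "s4"],
        )
    )


@pytest.fixture
def tiny_pheno():
    return PhenotypeTable(
        pd.DataFrame(
            {
                "class": [-1, -1, 1, 1],
                "time": [100.0, 300.0, 2000.0, 2500.0],
                "event": [1, 1, 0, 0],
                "batch": ["b1", "b2", "b1", "b2"],
            },
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
        )
    )


@pytest.fixture(scope="session")
def small_sim():
    """Shared medium-sized planted dataset (session-scoped: generated once)."""
    return simulate_dataset(SimConfig(n_genes=300, n_samples=120, seed=3))


def random_expr(n_genes, n_samples, seed, prefix="G"):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        pd.DataFrame(
            rng.standard_normal((n_genes, n_samples)),
            index=[f"{prefix}{i:04d}" for i in range(n_genes)],
            columns=[f"S{i:04d}" for i in range(n_samples)],
        )
    )
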
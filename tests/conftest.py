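import numpy as np
import pandas as pd
import pytest

from irgpair import GenePair


@pytest.fixture
def toy_expression() -> pd.DataFrame:
    """4 genes x 3 samples with a tie planted between GA and GB in s3."""
    return pd.DataFrame(
        [[5.0, 1.0, 3.0],
         [3.0, 2.0, 3.0],
         [1.0, 9.0, 4.0],
         [2.0, 2.0, 2.0]],
        index=["GA", "GB", "GC", "GD"],
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture
def toy_survival() -> pd.DataFrame:
    return pd.DataFrame(
        {"time": [12.0, 30.5, 7.0], "event": [1, 0, 1]},
        index=pd.Index(["s1", "s2", "s3"], name="sample"),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_survival(times, events, prefix="s") -> pd.DataFrame:
    return pd.DataFrame(
        {"time": np.asarray(times, dtype=float), "event": np.asarray(events, dtype=int)},
        index=pd.Index([f"{prefix}{i}" for i in range(len(times))], name="sample"),
    )


@pytest.fixture
def planted_config():
    from irgpair import SimulationConfig

    return SimulationConfig(
        n_genes=20,
        n_samples=200,
        seed=11,
        planted_pairs=[(GenePair("G0001", "G0002"), 1.0)],
    )
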
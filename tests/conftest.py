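import numpy as np
import pytest

from phylopart import Alignment, default_structured_config, simulate_dataset


@pytest.fixture
def toy_pair() -> Alignment:
    return Alignment.from_records({"a": "ACGT", "b": "ACGA"})


@pytest.fixture
def random_alignment() -> Alignment:
    """A 6 x 100 alignment with bases, ambiguity codes, N and gaps."""
    rng = np.random.default_rng(42)
    symbols = np.array(list("ACGT" * 10 + "N-RY"))
    mat = rng.choice(symbols, size=(6, 100))
    return Alignment.from_records(
        {f"s{i}": "".join(row) for i, row in enumerate(mat)}
    )


@pytest.fixture
def structured_dataset():
    """K=4 clades, d=0.03, theta=0.005, n=6 per clade, L=1284."""
    cfg = default_structured_config(seed=7)
    return simulate_dataset(cfg)
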
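import pytest

from ripseed.seeds import MirnaFamily
from ripseed.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def let7_family() -> MirnaFamily:
    # canonical let-7; seed (positions 2-8) is GAGGUAG
    return MirnaFamily(
        name="let-7", members=("cel-let-7",), mature_sequences=("UGAGGUAGUAGGUUGUAUAGUU",)
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic study shared across read-only tests."""
    return simulate_dataset(SimConfig(n_genes=60, n_bound=12, rng_seed=42))
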
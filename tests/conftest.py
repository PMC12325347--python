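import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from marinitax.pairwise_align import AlignParams
from marinitax.synthetic_data import ProteomePairSpec, simulate_proteome_pair


@pytest.fixture(scope="session")
def align_params() -> AlignParams:
    return AlignParams()


@pytest.fixture(scope="session")
def small_pair():
    """A 20+20 proteome pair with 10 orthologs at ~80% identity."""
    return simulate_proteome_pair(
        ProteomePairSpec(
            n_a=20, n_b=20, n_orth=10, target_identity_pct=80.0,
            length_range=(60, 120), seed=42,
        )
    )
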
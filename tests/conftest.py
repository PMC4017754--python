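import os
import sys

import pytest

sys.path.insert(0, os.path.dirname(__file__))  # make tests/_oracles.py importable

from g4conserve import AlignParams, ScanParams, ScoringParams


@pytest.fixture(scope="session")
def scan_params() -> ScanParams:
    return ScanParams()

@pytest.fixture(scope="session")
def align_params() -> AlignParams:
    return AlignParams()


@pytest.fixture(scope="session")
def scoring_params() -> ScoringParams:
    return ScoringParams()


def random_dna(rng, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet)) for _ in range(length))
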
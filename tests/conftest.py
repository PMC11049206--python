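import numpy as np
import pytest

from satmapper import SatDNAFamily

#: background composition used throughout: A+T-rich, like beetle genomes
BG_PROBS = {"A": 0.32, "C": 0.18, "G": 0.18, "T": 0.32}


def random_dna(n: int, rng: np.random.Generator) -> str:
    bases = list(BG_PROBS)
    return "".join(rng.choice(bases, p=list(BG_PROBS.values()), size=n))


@pytest.fixture(scope="session")
def monomer_141() -> str:
    rng = np.random.default_rng(20240322)
    return random_dna(141, rng)


@pytest.fixture(scope="session")
def family_141(monomer_141) -> SatDNAFamily:
    return SatDNAFamily.from_monomer(
        monomer_141, genus="Chrysolina", species="americana", rank=1
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
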
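import numpy as np
import pytest

from mirseed.seed_model import MatureMiRNA, derive_seed_sites, reverse_complement

# 21-mer insert of the miR-143 antisense oligo with perfect complementarity
# to mature miR-143; reverse-complementing it recovers the mature sequence.
MIR143_AS_INSERT = "GAGCTACAGTGCTTCATCTCA"
MIR143_MATURE = "TGAGATGAAGCACTGTAGCTC"

# HK2 3'UTR mutagenesis primer context: the wild-type 8mer seed site
# TCATCTCA was converted into TCATGACA
HK2_MUT_CONTEXT = "GTGTGATGAATAGCGAATCATGACAAATCCTTGAGCACTCAGTC"
HK2_WT_CONTEXT = "GTGTGATGAATAGCGAATCATCTCAAATCCTTGAGCACTCAGTC"


@pytest.fixture(scope="session")
def mir143() -> MatureMiRNA:
    return MatureMiRNA("miR-143", reverse_complement(MIR143_AS_INSERT))


@pytest.fixture(scope="session")
def mir143_sites(mir143):
    return derive_seed_sites(mir143)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=p))
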
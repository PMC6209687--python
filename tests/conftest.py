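import numpy as np
import pytest

from glacialdemog.seqdata import HaplotypeAlignment


def make_alignment(seqs, pops=None, locus="toy", ploidy_tag="nuclear-phased"):
    ids = [f"s{i}" for i in range(len(seqs))]
    if pops is None:
        pops = ["pop1"] * len(seqs)
    return HaplotypeAlignment(
        locus_name=locus,
        sequences=list(seqs),
        sample_ids=ids,
        population_of=dict(zip(ids, pops)),
        ploidy_tag=ploidy_tag,
    )


@pytest.fixture
def toy_alignment():
    """n=4, L=10; S=2 (sites 4 and 10), pair differences {1,2,2,1,1,0}."""
    return make_alignment(
        ["ACGTACGTAC", "ACGTACGTAT", "ACGAACGTAT", "ACGAACGTAT"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_alignment(rng, n, L, alphabet="ACGT"):
    letters = np.array(list(alphabet))
    M = letters[rng.integers(0, len(letters), size=(n, L))]
    return make_alignment(["".join(r) for r in M])
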
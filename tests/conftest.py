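import pytest

from foundercnv.simulate import Individual, Pedigree


@pytest.fixture
def trio() -> Pedigree:
    """Two unrelated founders and one child."""
    return Pedigree(
        [
            Individual("dad", None, None, "male", 0),
            Individual("mom", None, None, "female", 0),
            Individual("kid", "dad", "mom", "male", 1),
        ]
    )


@pytest.fixture
def sib_mating_pedigree() -> Pedigree:
    """Child of full sibs: the classic inbreeding closed-form case."""
    return Pedigree(
        [
            Individual("gf", None, None, "male", 0),
            Individual("gm", None, None, "female", 0),
            Individual("bro", "gf", "gm", "male", 1),
            Individual("sis", "gf", "gm", "female", 1),
            Individual("inbred", "bro", "sis", "female", 2),
        ]
    )
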
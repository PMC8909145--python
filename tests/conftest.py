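import random

import pytest
from hypothesis import strategies as st

from neosrm import fixtures
from neosrm.chem import AA_MONO_MASS

AA_LETTERS = sorted(AA_MONO_MASS)

peptide_sequences = st.text(
    alphabet=AA_LETTERS, min_size=1, max_size=15
)
mhc_length_sequences = st.text(alphabet=AA_LETTERS, min_size=8, max_size=12)


@pytest.fixture(scope="session")
def fx():
    """The packaged 11-target benchmark set."""
    return fixtures()


@pytest.fixture()
def rng():
    return random.Random(20240901)
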
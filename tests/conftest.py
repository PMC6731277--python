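import numpy as np
import pytest

from guidespec import CfdWeightTable, random_genome


@pytest.fixture(scope="session")
def weights():
    return CfdWeightTable.synthetic()


@pytest.fixture(scope="session")
def all_one_weights():
    """Degenerate table: every mismatch weight 1, every PAM weight 1."""
    mm = {(p, g, t): 1.0 for p in range(1, 21)
          for g in "ACGT" for t in "ACGT" if g != t}
    pam = {s1 + s2: 1.0 for s1 in "ACGT" for s2 in "ACGT"}
    return CfdWeightTable(mm, pam, source_label="all-one")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_genome():
    return random_genome(20_000, seed=11)


def random_spacer(rng):
    return "".join(rng.choice(list("ACGT"), size=20))
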
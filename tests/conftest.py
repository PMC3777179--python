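import numpy as np
import pytest

from pyrometh import (
    DegenerateSequence,
    generate_dispensation,
    packaged_assays,
    packaged_kit,
)


@pytest.fixture(scope="session")
def kit():
    """The commercial LINE1 kit's (template, vendor order) pair."""
    return packaged_kit()


@pytest.fixture(scope="session")
def kit_seq(kit):
    return kit[0]


@pytest.fixture(scope="session")
def kit_order(kit):
    return kit[1]


@pytest.fixture(scope="session")
def gen_order(kit_seq):
    """A generated, fully identifiable order for the kit template."""
    return generate_dispensation(kit_seq)


@pytest.fixture(scope="session")
def assays():
    return packaged_assays()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_degenerate(rng, max_len=40, max_sites=4) -> DegenerateSequence:
    """Random converted-template-like sequence (every Y followed by G)."""
    while True:
        n = int(rng.integers(1, max_len + 1))
        out = []
        while len(out) < n:
            b = "ACGTY"[int(rng.integers(0, 5))]
            if b == "Y":
                if len(out) + 2 > n:
                    continue
                out += ["Y", "G"]
            else:
                out.append(b)
        seq = "".join(out)
        if seq.count("Y") <= max_sites:
            return DegenerateSequence(bases=seq)
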
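import io

import pytest

from consalign import Alignment, SynthConfig, generate_truth, read_alignment


@pytest.fixture
def toy_alignment():
    """The 2-sequence, 3-column toy used across modules."""
    return read_alignment(io.StringIO(">a\nAC-\n>b\nA-G\n"))


@pytest.fixture
def gap_shift_pair():
    """Two alignments of sequences {a: 'A', b: 'A'} differing only in gap
    placement: one aligns them, one staggers them."""
    staggered = Alignment.from_rows([("a", "A-"), ("b", "-A")])
    aligned = Alignment.from_rows([("a", "A"), ("b", "A")])
    return staggered, aligned


def random_alignment(seed, n_sequences=4, length=30, gap_fraction=0.2):
    return generate_truth(
        SynthConfig(
            n_sequences=n_sequences,
            length=length,
            gap_fraction=gap_fraction,
            seed=seed,
        )
    )


@pytest.fixture
def random_alignment_factory():
    return random_alignment
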
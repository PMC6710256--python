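import numpy as np
import pytest

from sspred.io_formats import Alignment, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_alignment():
    """Rows {AA, AC, CC}: the worked example for sequence weighting."""
    return Alignment(
        query=ProteinRecord(id="q", sequence="AA"),
        rows=["AC", "CC"],
        include_query_row=True,
    )


def random_alignment(rng, length=None, n_rows=None, allow_gaps=True):
    """A random small query-anchored alignment for property tests."""
    from sspred.alphabet import AA20

    length = length or int(rng.integers(1, 9))
    n_rows = n_rows if n_rows is not None else int(rng.integers(0, 5))
    aas = list(AA20)
    query = "".join(rng.choice(aas, size=length))
    rows = []
    for _ in range(n_rows):
        chars = []
        for j in range(length):
            if allow_gaps and rng.random() < 0.2:
                chars.append("-")
            else:
                chars.append(str(rng.choice(aas)))
        rows.append("".join(chars))
    return Alignment(
        query=ProteinRecord(id="q", sequence=query), rows=rows, include_query_row=True
    )
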
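import numpy as np
import pytest

from scramblekit.design import (
    build_reference,
    his_module_design,
    random_segment_sequence,
)


@pytest.fixture(scope="session")
def his_design():
    """The package's default 7-gene HIS module (~20 kb, 8 lox sites)."""
    return his_module_design(seed=1)


@pytest.fixture(scope="session")
def toy_design():
    """A small 4-segment module for fast alignment tests."""
    rng = np.random.default_rng(7)
    lengths = {"GENA": 380, "GENB": 520, "GENC": 300, "GEND": 450}
    sequences = {name: random_segment_sequence(n, rng) for name, n in lengths.items()}
    layout = [
        {"order": i + 1, "segment_id": i + 1, "name": n, "role": "gene_cassette"}
        for i, n in enumerate(lengths)
    ]
    return build_reference(
        layout,
        sequences,
        left_flank=random_segment_sequence(120, rng),
        right_flank=random_segment_sequence(120, rng),
    )
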
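"""Shared fixtures: synthetic libraries generated at test time (no data files)."""

from __future__ import annotations

import numpy as np
import pytest

from lnpfusion import synthgen


@pytest.fixture(scope="session")
def small_library():
    """30 labelled lipids (6 heads x 5 tails), fixed seeds."""
    lib = synthgen.generate_library(n_heads=6, n_tails=5, seed=11)
    return synthgen.assign_labels(lib, noise_sd=0.5, seed=12)


@pytest.fixture(scope="session")
def cliff_library():
    """200-molecule library plus 20 injected single-atom cliff twins."""
    lib = synthgen.generate_library(n_heads=20, n_tails=10, seed=1)
    lib = synthgen.assign_labels(lib, seed=2)
    lib, pairs = synthgen.inject_cliffs(lib, n_pairs=20, gap_log2=5.0, seed=3)
    return lib, pairs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
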
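"""Shared fixtures: all test data is generated, nothing is loaded from disk."""

from __future__ import annotations

import numpy as np
import pytest

from teinvader import synthetic
from teinvader.io_formats import SequenceRecord
from teinvader.readscan import PipelineThresholds


@pytest.fixture(scope="session")
def element():
    """A synthetic iERV-like element: 514 bp LTRs, tandem repeat, gag/pol/env."""
    return synthetic.make_test_element(seed=1)


@pytest.fixture(scope="session")
def thresholds():
    return PipelineThresholds()


@pytest.fixture(scope="session")
def reference():
    return synthetic.simulate_genome(100_000, seed=21, name="ref")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def tiling_reads(source: str, read_length: int = 100, n_starts: int = 15,
                 depth: int = 2, prefix: str = "r") -> list[SequenceRecord]:
    """Error-free reads tiling ``source`` so every k-mer reaches ``depth``."""
    starts = sorted(list(np.linspace(0, len(source) - read_length, n_starts).astype(int)) * depth)
    return [
        SequenceRecord(f"{prefix}{i}", source[s : s + read_length])
        for i, s in enumerate(starts)
    ]
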
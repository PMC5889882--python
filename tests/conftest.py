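from __future__ import annotations

import numpy as np
import pytest

from lncpair import GenomicFeature


@pytest.fixture
def feat():
    """Factory for concise feature construction in tests."""

    def make(fid, start, end, strand, role="gene", lnc_class=None, chrom="chrI"):
        if role == "lncRNA" and lnc_class is None:
            lnc_class = "SUT"
        return GenomicFeature(fid, chrom, start, end, strand, role, lnc_class)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_feature(rng, fid, role, chrom="chrI", span=20_000, max_len=2_000):
    start = int(rng.integers(0, span))
    length = int(rng.integers(1, max_len))
    strand = "+" if rng.random() < 0.5 else "-"
    lnc_class = "SUT" if role == "lncRNA" else None
    return GenomicFeature(fid, chrom, start, start + length, strand, role, lnc_class)
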
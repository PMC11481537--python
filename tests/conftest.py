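"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the implementation's data paths: depth is
counted base by base with slice increments instead of a difference array,
containment and classification are all-pairs loops, and the ratio filter is
checked by exhaustive enumeration of retain/discard labelings.
"""

from __future__ import annotations

import numpy as np
import pytest

from proktx.io import ReadInterval


def bruteforce_depth(start: int, end: int, reads) -> np.ndarray:
    """Per-base read counting: add 1 over every covered base of every read."""
    depth = np.zeros(end - start, dtype=np.int64)
    for r in reads:
        depth[r.start - start : r.end - start] += 1
    return depth


def make_reads(intervals, strand="+", contig="chr1"):
    """[(start, end), ...] -> ReadInterval list with generated ids."""
    return [
        ReadInterval(contig, s, e, strand, f"r{i}")
        for i, (s, e) in enumerate(intervals, start=1)
    ]


def random_read_set(rng, *, span=10_000, max_reads=1000, contig="chr1", strand="+"):
    """A random pile of reads inside [0, span) for oracle comparisons."""
    n = int(rng.integers(1, max_reads + 1))
    starts = rng.integers(0, span - 1, size=n)
    lengths = rng.integers(1, np.maximum(2, span - starts), size=n)
    ends = np.minimum(starts + lengths, span)
    return [
        ReadInterval(contig, int(s), int(e), strand, f"r{i}")
        for i, (s, e) in enumerate(zip(starts, ends), start=1)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20_2409)
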
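"""Named random substreams derived from a single run seed.

Every stochastic stage of the pipeline draws from a stream keyed by the run
seed plus a stable name, so that stages are reproducible independently of
the order in which they run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _keys(names: tuple) -> list[int]:
    return [zlib.crc32(str(n).encode("utf-8")) for n in names]


def substream(seed: int, *names) -> np.random.Generator:
    """Return a Generator for the substream ``names`` of run ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *_keys(names)]))


def substream_seed(seed: int, *names) -> int:
    """A derived integer seed (< 2**31) for APIs that take a plain seed."""
    ss = np.random.SeedSequence([int(seed), *_keys(names)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
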
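"""Counter-based random-number streams.

Every stochastic component of the engine draws from a numpy ``Generator``
backed by the Philox counter-based bit generator, keyed by ``(seed, stream)``.
Distinct ``(seed, stream, substream)`` triples give statistically independent
streams without any serial hand-off, which is what makes history-partitioned
parallel execution and stream merging exact: the result for a fixed
``(seed, n_streams)`` pair is bitwise reproducible regardless of scheduling.
"""

from __future__ import annotations

import numpy as np

_SUBSTREAM_BITS = 20


def stream_generator(seed: int, stream: int = 0, substream: int = 0) -> np.random.Generator:
    """Return the Generator for a given (seed, stream, substream) address.

    ``stream`` indexes the parallel worker, ``substream`` the control point
    (or any other deterministic partition of the work within a stream).
    """
    if seed < 0 or stream < 0 or substream < 0:
        raise ValueError("seed, stream and substream must be non-negative")
    if substream >= 1 << _SUBSTREAM_BITS:
        raise ValueError("substream id too large")
    key = np.array([np.uint64(seed), np.uint64((stream << _SUBSTREAM_BITS) + substream)],
                   dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))
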
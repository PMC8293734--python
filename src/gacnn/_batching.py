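"""Seeded mini-batch cycling shared by the GA and gradient trainers."""

from __future__ import annotations

import numpy as np


class BatchCycler:
    """Yield mini-batches by cycling through the data in shuffled order.

    The index order is reshuffled at the start of every epoch with the
    provided generator, so the full schedule is determined by the seed.
    A batch never mixes epochs; the last batch of an epoch may be short.
    """

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        if n <= 0:
            raise ValueError("empty dataset")
        if batch_size <= 0:
            raise ValueError("batch_size must be positive")
        self.n = n
        self.batch_size = min(batch_size, n)
        self.rng = rng
        self._order = rng.permutation(n)
        self._pos = 0

    def next_batch(self) -> np.ndarray:
        if self._pos >= self.n:
            self._order = self.rng.permutation(self.n)
            self._pos = 0
        idx = self._order[self._pos : self._pos + self.batch_size]
        self._pos += self.batch_size
        return idx
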
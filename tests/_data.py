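"""Deterministic datasets used by several test modules."""

import numpy as np


def separable_xy(n: int, gap: float = 0.06, seed: int = 0):
    """Perfectly separable 1-d data: sign(x) decides the class, with an
    empty margin around 0 and exactly n/2 points per side, so the sample
    median (a candidate interval boundary) falls inside the gap."""
    half = n // 2
    x = np.concatenate([-np.linspace(gap, 1.0, half), np.linspace(gap, 1.0, half)])
    rng = np.random.default_rng(seed)
    order = rng.permutation(x.size)
    x = x[order]
    return x[:, None], np.sign(x)
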
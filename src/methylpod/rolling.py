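"""Circular rolling statistics over whole-chromosome tracks.

Window alignment: the window contributing to position ``i`` is
``[i - floor(w/2), i - floor(w/2) + w)`` on the circle. For odd widths this
is the usual symmetric window; for even widths the extra element sits on the
left. The same convention is used for every width (256, 768, 1024, 75 ...)
so rolling outputs of different widths stay mutually aligned.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def _check(x: np.ndarray, width: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if width < 1:
        raise ValueError("width must be >= 1")
    if width > len(x):
        raise ValueError("width exceeds track length")
    return x


def rolling_median_circular(x: np.ndarray, width: int) -> np.ndarray:
    """Rolling median with circular wrap; output length equals input length."""
    x = _check(x, width)
    n = len(x)
    half = width // 2
    # pad enough on both sides that every window is fully in-bounds
    z = np.concatenate([x[n - width:], x, x[:width]])
    s = pd.Series(z).rolling(width).median().to_numpy()
    # rolling(width) at index j summarises z[j-width+1 : j+1];
    # we want the window starting at (width + i - half), ending at j below
    idx = np.arange(n) + 2 * width - half - 1
    return s[idx]


def rolling_mean_circular(x: np.ndarray, width: int) -> np.ndarray:
    """Rolling mean with circular wrap, same alignment as the median."""
    x = _check(x, width)
    n = len(x)
    half = width // 2
    z = np.concatenate([x[n - width:], x, x[:width]])
    cs = np.concatenate([[0.0], np.cumsum(z)])
    idx = np.arange(n) + width - half  # window start within z
    return (cs[idx + width] - cs[idx]) / width
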
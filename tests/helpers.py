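"""Independent oracles shared across test modules."""

import numpy as np


def direct_correlation(pixels_a: np.ndarray, pixels_b: np.ndarray) -> np.ndarray:
    """Brute-force normalized spatial correlation with periodic shifts.

    A double loop over every lag using np.roll, indexed by lag modulo the
    image size — deliberately FFT-free so it can vouch for the FFT path.
    """
    a = np.asarray(pixels_a, float)
    b = np.asarray(pixels_b, float)
    da, db = a - a.mean(), b - b.mean()
    h, w = a.shape
    out = np.empty((h, w))
    for xi in range(h):
        for eta in range(w):
            out[xi, eta] = np.mean(da * np.roll(db, (-xi, -eta), axis=(0, 1)))
    return out / (a.mean() * b.mean())


def oracle_lag(oracle: np.ndarray, lag_row: int, lag_col: int) -> float:
    h, w = oracle.shape
    return oracle[lag_row % h, lag_col % w]
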
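"""Independent brute-force oracles shared by the test modules."""

import numpy as np

from perturbnet import synthetic as syn


def brute_force_cooks(spots: np.ndarray, c_i: float) -> np.ndarray:
    """Leave-one-out Cook's distance: refit without each point and compare
    fitted values, D_m = sum_k (yhat_k - yhat_k^(m))^2 / (p s^2)."""
    conc = np.array(syn.DILUTION_FRACTIONS) * c_i
    A = np.column_stack([np.ones(4), conc])
    beta, *_ = np.linalg.lstsq(A, spots, rcond=None)
    yhat = A @ beta
    rss = np.sum((spots - yhat) ** 2)
    s2 = rss / 2  # n - p = 4 - 2
    out = np.zeros(4)
    if rss <= 1e-20 * max(1.0, float(spots @ spots)):
        return out
    for m in range(4):
        keep = np.ones(4, dtype=bool)
        keep[m] = False
        b_m, *_ = np.linalg.lstsq(A[keep], spots[keep], rcond=None)
        out[m] = np.sum((yhat - A @ b_m) ** 2) / (2 * s2)
    return out
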
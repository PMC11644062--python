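"""Independent naive-loop oracles shared by the test modules.

These deliberately avoid the vectorized/prefix-sum code paths used by the
package so that agreement between the two is a meaningful check.
"""

import numpy as np

from canopyseg import GrayHistogram


def random_hist(rng, L, sparsity=0.3):
    counts = rng.integers(0, 50, size=L)
    counts[rng.random(L) < sparsity] = 0
    if np.count_nonzero(counts) < 3:
        counts[[0, L // 2, L - 1]] = 5
    return GrayHistogram(
        L=L, counts=counts, proportions=counts / counts.sum(), value_range=(0.0, 1.0)
    )


def naive_sigma2(hist, thresholds):
    """Between-class variance by per-class accumulation over levels.

    Sums accumulate sequentially in ascending level order, so adding a
    zero-mass level leaves every partial sum bitwise unchanged — a
    threshold moving across empty levels yields exactly equal variances,
    the same plateau structure the search's tie-break rule operates on.
    """
    p = hist.proportions
    mu0 = 0.0
    for level in range(hist.L):
        mu0 += level * p[level]
    edges = [-1, *thresholds, hist.L - 1]
    sigma = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        mass, moment = 0.0, 0.0
        for level in range(lo + 1, hi + 1):
            mass += p[level]
            moment += level * p[level]
        if mass > 0:
            mu = moment / mass
            sigma += mass * (mu - mu0) ** 2
    return sigma


def naive_median3x3(data):
    """Sliding-window median with edge-reflection padding."""
    padded = np.pad(data, 1, mode="symmetric")
    out = np.empty_like(data, dtype=float)
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            out[i, j] = np.median(padded[i : i + 3, j : j + 3])
    return out


def naive_open(mask, r=1):
    """Erosion then dilation with a (2r+1)-square element, explicit loops."""
    side = 2 * r + 1
    padded = np.pad(mask, r, constant_values=False)
    eroded = np.zeros_like(mask)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            eroded[i, j] = padded[i : i + side, j : j + side].all()
    padded = np.pad(eroded, r, constant_values=False)
    dilated = np.zeros_like(mask)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            dilated[i, j] = padded[i : i + side, j : j + side].any()
    return dilated
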
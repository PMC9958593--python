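"""Independent oracles used by unit and acceptance tests.

These deliberately re-derive quantities through a different computational
path than the package (plain loops / FFT), so agreement is meaningful.
"""

import numpy as np


def sampen_bruteforce(x, m, r):
    """O(N^2) pair counting straight from the textbook definition.

    Templates of length m and m+1 are formed for i = 0..N-m-1; ordered pairs
    i != j with Chebyshev distance strictly below r are counted at both
    lengths and SampEn = -ln(A/B).
    """
    x = [float(v) for v in x]
    n = len(x) - m
    count_m = 0
    count_m1 = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = 0.0
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
            if d < r:
                count_m += 1
                t = abs(x[i + m] - x[j + m])
                if t > d:
                    d = t
                if d < r:
                    count_m1 += 1
    if count_m == 0 or count_m1 == 0:
        return float("nan")
    return -np.log(count_m1 / count_m)


def sampen_matrix(x, m, r):
    """Second independent path: full distance matrices via broadcasting."""
    x = np.asarray(x, dtype=float)
    n = len(x) - m
    tm = np.stack([x[i : i + m] for i in range(n)])
    tm1 = np.stack([x[i : i + m + 1] for i in range(n)])
    dm = np.abs(tm[:, None, :] - tm[None, :, :]).max(axis=-1)
    dm1 = np.abs(tm1[:, None, :] - tm1[None, :, :]).max(axis=-1)
    off = ~np.eye(n, dtype=bool)
    b = int(((dm < r) & off).sum())
    a = int(((dm1 < r) & off).sum())
    if b == 0 or a == 0:
        return float("nan")
    return -np.log(a / b)


def fft_band_power(x, fs, lo, hi):
    """Band power from the raw periodogram (rectangular window)."""
    spec = np.abs(np.fft.rfft(np.asarray(x, dtype=float))) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return float(spec[(freqs >= lo) & (freqs < hi)].sum())


def fft_band_ratios(x, fs):
    """(theta, alpha, beta) fractions of total 0.5-30 Hz power via FFT."""
    total = fft_band_power(x, fs, 0.5, 30.0)
    return tuple(
        fft_band_power(x, fs, lo, hi) / total
        for lo, hi in ((4.0, 8.0), (8.0, 14.0), (14.0, 30.0))
    )
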
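"""Independent brute-force oracles shared across test modules.

These deliberately avoid the package's vectorised implementations:
plain double loops and a full (unbanded) dynamic program.
"""

import numpy as np


def oracle_autocorr(w, c, n):
    """Energy-normalised lag-n correlation by direct summation."""
    num = sum(w[c + nu] * w[c + nu - n] for nu in range(n))
    e_right = sum(w[c + nu] ** 2 for nu in range(n))
    e_left = sum(w[c + nu - n] ** 2 for nu in range(n))
    denom = (e_right * e_left) ** 0.5
    return num / denom if denom > 0 else 0.0


def oracle_amdf(w, c, n):
    d = sum(abs(w[c + nu] - w[c + nu - n]) for nu in range(n)) / n
    return 1.0 / (1e-12 + d)


def oracle_map(w, c, n):
    return max(w[c + nu] + w[c + nu - n] for nu in range(n))


def oracle_dtw_full(a, b):
    """Unbanded DTW with |.| local cost, full dynamic program."""
    n, m = len(a), len(b)
    dp = np.full((n + 1, m + 1), np.inf)
    dp[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = abs(a[i - 1] - b[j - 1])
            dp[i, j] = cost + min(dp[i - 1, j], dp[i, j - 1], dp[i - 1, j - 1])
    return dp[n, m]


def periodic_window(period, nmax, kind="cos"):
    """A strictly periodic analysis window of length 2*nmax + 1."""
    nu = np.arange(-nmax, nmax + 1)
    if kind == "cos":
        return np.cos(2 * np.pi * nu / period)
    if kind == "spikes":
        w = np.zeros_like(nu, dtype=float)
        w[(nu % period) == 0] = 1.0
        return w
    raise ValueError(kind)
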
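"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorized implementations: plain
loops and direct formula evaluation only.
"""

import numpy as np


def exhaustive_best_arc(x, min_width):
    """Brute-force scan of every arc (i, j] for the two-sample t-like
    statistic between in-arc and out-of-arc values; returns (i, j, t)."""
    x = np.asarray(x, float)
    n = len(x)
    s = float(np.std(x, ddof=1))
    best = (0, n, 0.0)
    for i in range(0, n - min_width + 1):
        for j in range(i + min_width, n + 1):
            k = j - i
            if n - k < min_width or n - k == 0:
                continue
            mean_in = float(np.mean(x[i:j]))
            mean_out = (float(np.sum(x)) - float(np.sum(x[i:j]))) / (n - k)
            t = abs(mean_in - mean_out) / (s * np.sqrt(1.0 / k + 1.0 / (n - k)))
            if t > best[2]:
                best = (i, j, t)
    return best
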
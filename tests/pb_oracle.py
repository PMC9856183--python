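"""Brute-force Passing–Bablok oracle, independent of the library code.

Enumerates every pairwise slope with plain Python loops and applies the
shifted-median rule directly; used to cross-check the estimator on small
instances.
"""

import math


def pb_slope_intercept(x, y):
    n = len(x)
    slopes = []
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            dy = y[j] - y[i]
            if dx == 0:
                if dy == 0:
                    continue
                slopes.append(math.inf if dy > 0 else -math.inf)
            else:
                s = dy / dx
                if s != -1.0:
                    slopes.append(s)
    if not slopes:
        raise ValueError("no valid slopes")
    slopes.sort()
    N = len(slopes)
    K = sum(1 for s in slopes if s < -1.0)

    def at(pos):  # 1-indexed, offset K, clipped
        return slopes[min(max(pos + K, 1), N) - 1]

    if N % 2 == 1:
        b = at((N + 1) // 2)
    else:
        b = 0.5 * (at(N // 2) + at(N // 2 + 1))
    if not math.isfinite(b):
        raise ValueError("median slope is not finite")
    residuals = sorted(yi - b * xi for xi, yi in zip(x, y))
    m = len(residuals)
    if m % 2 == 1:
        a = residuals[m // 2]
    else:
        a = 0.5 * (residuals[m // 2 - 1] + residuals[m // 2])
    return b, a
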
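"""Independent brute-force oracles used by the acceptance tests.

These re-derive expected results with a different algorithmic structure
from the package implementation and must stay that way.
"""

import numpy as np


def brute_force_cutoff(signals):
    """Pure-python enumeration of the tangent point: evaluate the
    points-on-or-below count at every integer candidate and apply the
    largest-x tie-break."""
    s = sorted(max(float(v), 0.0) for v in signals)
    n = len(s)
    m = (s[-1] - s[0]) / n
    best_x, best_count = None, None
    for x in range(1, n + 1):
        count = 0
        for j in range(1, n + 1):
            if s[j - 1] <= s[x - 1] + m * (j - x):
                count += 1
        if best_count is None or count <= best_count:
            best_x, best_count = x, count
    return s[best_x - 1], best_x


def brute_force_cutoff_fast(signals):
    """Same enumeration with the inner point count vectorized, so that
    thousands of instances stay cheap. Cross-checked against the
    pure-python version."""
    s = np.sort(np.maximum(np.asarray(signals, dtype=float), 0.0))
    n = s.size
    m = (s[-1] - s[0]) / n
    j = np.arange(1, n + 1)
    best_x, best_count = None, None
    for x in range(1, n + 1):
        count = int(np.count_nonzero(s <= s[x - 1] + m * (j - x)))
        if best_count is None or count <= best_count:
            best_x, best_count = x, count
    return float(s[best_x - 1]), best_x
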
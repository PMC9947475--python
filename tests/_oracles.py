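"""Independent brute-force oracles shared by the test suite."""

import numpy as np


def brute_force_tau_b(x, y):
    """Exhaustive pairwise concordance count with tie correction."""
    x, y = np.asarray(x), np.asarray(y)
    n = x.size
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = np.sign(x[j] - x[i])
            sy = np.sign(y[j] - y[i])
            if sx == 0 and sy == 0:
                continue
            if sx == 0:
                tx += 1
            elif sy == 0:
                ty += 1
            elif sx == sy:
                c += 1
            else:
                d += 1
    denom = np.sqrt((c + d + tx) * (c + d + ty))
    return (c - d) / denom
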
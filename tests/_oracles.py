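"""Independent brute-force oracles used by several test modules."""

import numpy as np


def brute_force_stump_gini(values, labels):
    """Exhaustive enumeration over every possible binary split."""
    v = np.asarray(values, float)
    y = np.asarray(labels)
    classes = list(dict.fromkeys(y))

    def node(yy):
        if len(yy) == 0:
            return 0.0
        p = np.array([(yy == c).mean() for c in classes])
        return 1.0 - (p ** 2).sum()

    best = node(y) if len(np.unique(v)) == 1 else np.inf
    uniq = np.sort(np.unique(v))
    for t in (uniq[:-1] + uniq[1:]) / 2:
        left = v <= t
        g = (left.sum() * node(y[left]) + (~left).sum() * node(y[~left])) / len(v)
        best = min(best, g)
    return best
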
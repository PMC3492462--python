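"""Small statistical helpers shared across stages."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = ["safe_ttest", "correlation"]


def safe_ttest(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test robust to zero-variance groups.

    Noise-free synthetic data yields groups with exactly zero variance,
    where the t statistic is undefined.  The limiting behaviour is used
    instead: if both groups are constant, p = 1 when the means agree and
    p = 0 (t = ±inf) when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    with warnings.catch_warnings():
        # near-identical groups trigger a benign precision warning; the
        # resulting extreme t / tiny p is the correct limiting answer
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def correlation(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p (generic marker co-response utility)."""
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)
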
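"""Small shared statistical primitives.

Multiple-testing correction and the pooled two-proportion z-test used by the
summary reports. Heavier machinery (NB tests, NG86, Fisher classification)
lives in the dedicated modules.
"""

from __future__ import annotations

import math

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr", "proportion_ztest"]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Parameters
    ----------
    pvalues : array-like of float in [0, 1]

    Returns
    -------
    numpy.ndarray of q-values, same order as the input. Elementwise
    ``q >= p`` and q is monotone non-decreasing in the sorted order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test.

    Z = (p1 - p2) / sqrt(p*(1-p*)(1/n1 + 1/n2)) with p* the pooled
    proportion. Returns ``(z, two-sided p)``. Z is positive when the first
    proportion is larger.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError("successes must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    denom = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if denom == 0.0:
        # both proportions are 0 or both are 1: no evidence of a difference
        return 0.0, 1.0
    from scipy.stats import norm

    z = (p1 - p2) / denom
    return z, 2.0 * norm.sf(abs(z))
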
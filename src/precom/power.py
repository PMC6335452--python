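"""A-priori sample-size calculation for a paired-samples t-test.

Power is evaluated exactly under the noncentral-t distribution: for n
pairs, the test statistic has df = n - 1 and noncentrality d_z * sqrt(n),
where d_z is the standardized mean of the paired differences.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["paired_ttest_power", "required_sample_size"]

_MAX_N = 1_000_000


def paired_ttest_power(n: int, effect_size: float, alpha: float = 0.05,
                       tails: int = 2) -> float:
    """Exact power of a paired t-test with ``n`` pairs."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = effect_size * np.sqrt(n)
    if tails == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(1.0 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    if tails == 1:
        tcrit = stats.t.ppf(1.0 - alpha, df)
        return float(1.0 - stats.nct.cdf(tcrit, df, nc))
    raise ValueError("tails must be 1 or 2")


def required_sample_size(effect_size: float, alpha: float = 0.05,
                         power: float = 0.95, tails: int = 2) -> int:
    """Smallest n whose paired t-test reaches the target power.

    For a moderate effect (d_z = 0.5) at alpha = 0.05 two-tailed and power
    0.95 this yields n = 54.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0.0 < power < 1.0:
        raise ValueError("power must lie in (0, 1)")
    if effect_size <= 0.0:
        raise ValueError("effect_size must be positive")
    # bracket geometrically, then walk back to the smallest sufficient n
    n = 2
    while paired_ttest_power(n, effect_size, alpha, tails) < power:
        n *= 2
        if n > _MAX_N:
            raise ValueError("target power unreachable at any practical n")
    lo, hi = max(n // 2, 2), n
    while lo < hi:
        mid = (lo + hi) // 2
        if paired_ttest_power(mid, effect_size, alpha, tails) >= power:
            hi = mid
        else:
            lo = mid + 1
    return int(lo)
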
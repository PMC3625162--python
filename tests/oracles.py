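"""Independent brute-force oracles used to check the statistical routines.

These deliberately avoid the code paths (and libraries' test functions) they
validate: the Mann-Whitney oracle enumerates every assignment of the pooled
observations to the two groups; the Fisher oracle enumerates the
hypergeometric support with fixed margins.
"""

from itertools import combinations

import numpy as np
from scipy.stats import hypergeom


def mw_exact_oracle(a, b, alternative="two-sided") -> float:
    """Exact Mann-Whitney p by full enumeration (tie-free inputs only)."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    na = len(a)
    us = []
    for idx in combinations(range(len(pooled)), na):
        chosen = set(idx)
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        us.append(sum(1 for x in ga for y in gb if x > y))
    us = np.asarray(us)
    u_obs = sum(1 for x in a for y in b if x > y)
    p_less = float(np.mean(us <= u_obs))
    p_greater = float(np.mean(us >= u_obs))
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))


def fisher_exact_oracle(table) -> float:
    """Two-sided Fisher p: sum of hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    r1 = a + b
    n = a + b + c + d
    c1 = a + c
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    pmf = {x: hypergeom.pmf(x, n, c1, r1) for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))
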
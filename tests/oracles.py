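"""Independent oracles used to cross-check the closed-form statistics.

These deliberately avoid the implementation's code path: the KS statistics
are recomputed by a full O(n) scan of the query-set step function against
the uniform line, rather than the closed-form maximum over query positions.
"""

from __future__ import annotations

import numpy as np


def running_sum_ab(query_ranks, n: int) -> tuple[float, float]:
    """Full-scan running-sum KS statistics for a query set of ranks in 1..n.

    Walk every position k = 0..n of the ranking, tracking the query-set
    empirical CDF F(k) = (#query ranks <= k)/t against the uniform line
    k/n.  Returns

    * ``a`` = the maximum of F(k) - k/n over k = 1..n (maximal positive
      deviation, attained where the step function leads the line), and
    * ``b`` = minus the maximum of k/n - F(k) over k = 0..n (maximal lag).
    """
    ranks = set(int(r) for r in query_ranks)
    t = len(ranks)
    if t == 0:
        raise ValueError("empty query set")
    hits = 0
    best_lead = -np.inf
    best_lag = 0.0 - 0.0  # k = 0 term: F(0) = 0, line = 0
    for k in range(1, n + 1):
        if k in ranks:
            hits += 1
        f = hits / t
        line = k / n
        best_lead = max(best_lead, f - line)
        best_lag = max(best_lag, line - f)
    return float(best_lead), float(-best_lag)


def random_instance(rng: np.random.Generator, max_n: int = 200):
    """A random (universe size, query rank set) instance for oracle checks."""
    n = int(rng.integers(5, max_n + 1))
    t = int(rng.integers(1, n + 1))
    ranks = rng.choice(np.arange(1, n + 1), size=t, replace=False)
    return n, np.sort(ranks)
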
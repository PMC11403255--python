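"""Independent brute-force oracles used to cross-check the implementation.

These deliberately restate the logic in a different form from the package
(disjoint predicate sets instead of a decision tree; full enumeration instead
of closed-form rank distributions) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def oracle_spine_class(length: float, head: float, neck: float) -> str:
    """Four disjoint predicate sets covering geometry space.

    Conventions match the package: neck == 0 means an infinite head-to-neck
    ratio; head == 0 means an infinite length-to-head ratio.
    """
    r = math.inf if neck == 0 else head / neck
    lh = math.inf if head == 0 else length / head

    mushroom = r > 1.1 and head > 0.35
    stubby = r <= 1.1 and lh <= 3.0
    elongated = (r > 1.1 and head <= 0.35) or (r <= 1.1 and lh > 3.0)
    filopodium = elongated and length >= 3.0
    thin = elongated and length < 3.0

    flags = {
        "mushroom": mushroom,
        "stubby": stubby,
        "filopodium": filopodium,
        "thin": thin,
    }
    chosen = [k for k, v in flags.items() if v]
    assert len(chosen) == 1, f"predicates not disjoint/total at {(length, head, neck)}"
    return chosen[0]


def oracle_mwu_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all rank splits.

    Valid only for tie-free pooled samples.
    """
    x, y = list(x), list(y)
    n1, n = len(x), len(x) + len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == n, "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    offset = n1 * (n1 + 1) / 2
    u_obs = sum(rank[v] for v in x) - offset
    us = np.array(
        [sum(c) - offset for c in combinations(range(1, n + 1), n1)]
    )
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)
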
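"""Brute-force oracle for the dip statistic, independent of the GCM/LCM code.

The dip of a sample is min over unimodal distribution functions G of
sup_x |F_n(x) - G(x)|.  For a sorted sample x_1 < ... < x_n this oracle
enumerates every mode placement "at data point x_m, atom allowed" (the CDF
may jump at its mode) and for each solves a small linear program in the
values g_i = G(x_i), the left limit at the mode, and the distance D:

    minimize D subject to
      band:       i/n - D <= g_i <= (i-1)/n + D         (continuity points)
      atom at x_m: left value in (m-1)/n +- D, right value in m/n +- D
      monotone:   g_1 <= ... <= g_n, all in [0, 1]
      convex on the points left of the mode, concave right of it.

A mode strictly inside a gap (x_k, x_{k+1}) is always dominated by a mode at
one of the gap's endpoints: convexity forces the CDF to keep climbing at at
least its last left-hand slope until the mode and concavity forces at least
the next right-hand slope after it, so sliding the mode to whichever
endpoint has the smaller adjacent slope never increases the sup distance.
Mode placements outside [x_1, x_n] are likewise dominated by atoms at the
extreme points.  Enumerating the n atom placements is therefore exhaustive.

Left of x_1 the CDF can be extended flat (convexity allows slope 0 first),
so g_1 <= D is the only tail constraint and it is implied by the band.

Only used on samples with distinct values; tie cases are covered by the
analytic values asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _solve(c, a_ub, b_ub, bounds):
    res = linprog(
        c,
        A_ub=np.asarray(a_ub, dtype=float),
        b_ub=np.asarray(b_ub, dtype=float),
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": 1e-10,
            "dual_feasibility_tolerance": 1e-10,
        },
    )
    return res.fun if res.status == 0 else np.inf


def _mode_at_point(x: np.ndarray, m: int) -> float:
    """Minimal D with the mode exactly at data point x_{m+1} (0-based m) and a
    possible atom there: separate left/right values at the mode."""
    n = len(x)
    # variables: g_0..g_{n-1} (right/CDF values), gm (left value at mode), D
    nv = n + 2
    gm, dvar = n, n + 1
    c = np.zeros(nv)
    c[dvar] = 1.0
    rows, rhs = [], []

    def row():
        rows.append(np.zeros(nv))
        rhs.append(0.0)
        return rows[-1], len(rows) - 1

    for i in range(n):
        lo = (i + 1) / n if i != m else (m + 1) / n  # lower band
        hi = i / n if i != m else (m + 1) / n  # upper band; at mode both sides are i+1/n
        r, j = row()
        r[i], r[dvar] = -1.0, -1.0
        rhs[j] = -lo
        r, j = row()
        r[i], r[dvar] = 1.0, -1.0
        rhs[j] = hi
    # left value at the mode approximates the lower ECDF step m/n
    r, j = row()
    r[gm], r[dvar] = -1.0, -1.0
    rhs[j] = -m / n
    r, j = row()
    r[gm], r[dvar] = 1.0, -1.0
    rhs[j] = m / n
    # monotone: g_0 <= .. <= g_{m-1} <= gm <= g_m <= .. <= g_{n-1}
    for i in range(n - 1):
        if i == m - 1:
            continue
        r, _ = row()
        r[i], r[i + 1] = 1.0, -1.0
    if m > 0:
        r, _ = row()
        r[m - 1], r[gm] = 1.0, -1.0
    r, _ = row()
    r[gm], r[m] = 1.0, -1.0
    # convex through (x_0..x_{m-1}, g) and (x_m, gm)
    left_idx = list(range(m)) + [gm]
    left_x = list(x[:m]) + [x[m]]
    for t in range(1, len(left_x) - 1):
        dl, dr = left_x[t] - left_x[t - 1], left_x[t + 1] - left_x[t]
        r, _ = row()
        r[left_idx[t - 1]] += -1.0 / dl
        r[left_idx[t]] += 1.0 / dl + 1.0 / dr
        r[left_idx[t + 1]] += -1.0 / dr
    # concave through (x_m, g_m) and (x_{m+1}..x_{n-1}, g)
    for i in range(m + 1, n - 1):
        dl, dr = x[i] - x[i - 1], x[i + 1] - x[i]
        r, _ = row()
        r[i - 1] += 1.0 / dl
        r[i] += -1.0 / dl - 1.0 / dr
        r[i + 1] += 1.0 / dr
    bounds = [(0.0, 1.0)] * (n + 1) + [(0.0, None)]
    return _solve(c, rows, rhs, bounds)


def dip_oracle(values) -> float:
    """Exact dip by enumeration over mode placements (distinct values only)."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(x)
    if n < 2:
        raise ValueError("need at least two values")
    if len(np.unique(x)) != n:
        raise ValueError("oracle requires distinct values")
    best = np.inf
    for m in range(n):
        best = min(best, _mode_at_point(x, m))
    return float(best)
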
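"""Brute-force minimax oracle for Hartigan's dip, via linear programming.

Independent of the package's gcm/lcm construction: for every candidate mode
(each unique sample value), the nearest unimodal CDF is found by an LP over
piecewise-linear CDFs with knots at the sample values.  The CDF must be
convex left of the mode and concave right of it, nondecreasing, with an atom
permitted at the mode; the deviation is measured against both the left and
right limits of the empirical CDF at every knot (which bounds the sup norm
everywhere, since both functions are monotone between knots).  The dip is the
smallest optimum over modes.

Restricting to piecewise-linear fits with knot modes is exact: the chord
interpolant of any unimodal CDF has a unimodal slope sequence, hence is
itself unimodal with a mode at a knot.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def dip_bruteforce(values) -> float:
    v = np.asarray(values, dtype=float).ravel()
    x, counts = np.unique(v, return_counts=True)
    n = v.size
    k = len(x)
    if k == 1:
        return 0.0
    f_right = np.cumsum(counts) / n
    f_left = f_right - counts / n

    best = np.inf
    for mode in range(k):
        val = _fit_mode(x, f_left, f_right, mode)
        if val < best:
            best = val
    return float(best)


def _fit_mode(x, f_left, f_right, mode) -> float:
    k = len(x)
    # variables: g[0..k-1] (CDF right values at knots), gL (left value at the
    # mode knot), t (sup deviation)
    ngl = k
    nt = k + 1
    nvar = k + 2

    rows, rhs = [], []

    def add(coef: dict[int, float], b: float) -> None:
        row = np.zeros(nvar)
        for j, c in coef.items():
            row[j] = c
        rows.append(row)
        rhs.append(b)

    def left_var(j: int) -> int:
        return ngl if j == mode else j

    # |g_j - F(x_j)| <= t and |G(x_j^-) - F(x_j^-)| <= t
    for j in range(k):
        add({j: 1.0, nt: -1.0}, f_right[j])
        add({j: -1.0, nt: -1.0}, -f_right[j])
        lj = left_var(j)
        add({lj: 1.0, nt: -1.0}, f_left[j])
        add({lj: -1.0, nt: -1.0}, -f_left[j])

    # monotone: right value at knot j <= left value at knot j+1; jump at mode
    for j in range(k - 1):
        add({j: 1.0, left_var(j + 1): -1.0}, 0.0)
    add({ngl: 1.0, mode: -1.0}, 0.0)  # gL <= g at the mode

    # segment j spans knots j -> j+1, from right value g_j to left value
    # L(j+1); slope s_j = (L(j+1) - g_j) / dx_j
    dx = np.diff(x)

    def slope_coef(j: int, sign: float, coef: dict[int, float]) -> None:
        c = sign / dx[j]
        coef[left_var(j + 1)] = coef.get(left_var(j + 1), 0.0) + c
        coef[j] = coef.get(j, 0.0) - c

    # convex (slopes nondecreasing) among segments ending at or before mode
    for j in range(1, mode):
        coef: dict[int, float] = {}
        slope_coef(j - 1, 1.0, coef)
        slope_coef(j, -1.0, coef)
        add(coef, 0.0)
    # concave (slopes nonincreasing) among segments starting at or after mode
    for j in range(mode + 1, k - 1):
        coef = {}
        slope_coef(j, 1.0, coef)
        slope_coef(j - 1, -1.0, coef)
        add(coef, 0.0)

    c = np.zeros(nvar)
    c[nt] = 1.0
    bounds = [(0.0, 1.0)] * (k + 1) + [(0.0, None)]
    res = linprog(
        c, A_ub=np.array(rows), b_ub=np.array(rhs), bounds=bounds, method="highs"
    )
    if not res.success:  # pragma: no cover - the LP is always feasible
        raise RuntimeError(f"oracle LP failed at mode {mode}: {res.message}")
    return res.fun
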
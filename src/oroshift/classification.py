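"""Topography classes from elevation-value distributions.

A mountain range's area-elevation distribution is summarized by two
scale-free statistics: Hartigan's dip (departure of the empirical CDF from
the nearest unimodal CDF, in sup norm) and the moment coefficient of skewness
g1 = m3 / m2^(3/2) ("Type-I" skewness, no small-sample correction).  Classes:

* hourglass — dip > 0.01 and bootstrap p < 0.05 (significantly bimodal),
  irrespective of skew;
* pyramid — otherwise, g1 >= 0.5 (area concentrated at low elevations);
* inverse pyramid — g1 <= -0.5 (area concentrated at high elevations);
* diamond — the remainder (mid-elevation area peak, near-symmetric);
* intensified — the intact-land value set is empty: no intact area remains
  once cells under intense human pressure are removed.

The dip statistic is computed exactly by the iterative greatest-convex-
minorant / least-concave-majorant construction on the empirical CDF; the
bootstrap p-value calibrates the observed dip against dips of uniform(0, 1)
samples of matched size (the standard null for the test).  Null tables are
cached per (n, n_boot, seed) — they do not depend on the data.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError

__all__ = [
    "MountainClass",
    "ClassificationResult",
    "dip_statistic",
    "dip_pvalue",
    "skewness_type1",
    "classify",
]


class MountainClass(str, enum.Enum):
    PYRAMID = "pyramid"
    DIAMOND = "diamond"
    HOURGLASS = "hourglass"
    INVERSE_PYRAMID = "inverse_pyramid"
    INTENSIFIED = "intensified"


@dataclass
class ClassificationResult:
    dip: float
    dip_p: float
    skewness: float
    mclass: MountainClass
    n: int
    case: str  # "total" or "intact"


# ---------------------------------------------------------------------------
# Hartigan's dip statistic
# ---------------------------------------------------------------------------


def _lower_hull(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Indices of the greatest convex minorant touch points of (x, y)."""
    hull: list[int] = []
    for i in range(len(x)):
        # pop while the previous segment's slope >= the new segment's slope
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (y[b] - y[a]) * (x[i] - x[b]) >= (y[i] - y[b]) * (x[b] - x[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _upper_hull(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Indices of the least concave majorant touch points of (x, y)."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (y[b] - y[a]) * (x[i] - x[b]) <= (y[i] - y[b]) * (x[b] - x[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def dip_statistic(values) -> float:
    """Hartigan's dip: minimax distance from the empirical CDF to the
    nearest unimodal CDF.

    Computed on the unique values with their multiplicities.  The statistic
    is location/scale invariant and bounded below by 1/(2n) for samples with
    at least two distinct values; a constant sample (a point mass, which is
    itself unimodal) has dip 0.

    Requires at least 4 finite values.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 4:
        raise DegenerateSampleError("dip statistic requires at least 4 values")
    if not np.all(np.isfinite(v)):
        raise DegenerateSampleError("dip statistic requires finite values")
    xu, counts = np.unique(v, return_counts=True)
    n = v.size
    if len(xu) == 1:
        return 0.0
    f_right = np.cumsum(counts) / n  # empirical CDF at each unique value
    f_left = f_right - counts / n  # its left limits

    lo, hi = 0, len(xu) - 1
    best = 0.0
    while True:
        xs = xu[lo : hi + 1]
        yl = f_left[lo : hi + 1]
        yr = f_right[lo : hi + 1]
        k = len(xs)
        gcm_t = np.array(_lower_hull(xs, yl))  # fitted to the lower step corners
        lcm_t = np.array(_upper_hull(xs, yr))  # fitted to the upper step corners
        gcm = np.interp(xs, xs[gcm_t], yl[gcm_t])
        lcm = np.interp(xs, xs[lcm_t], yr[lcm_t])
        gap = lcm - gcm

        d_gcm = gap[gcm_t].max()
        d_lcm = gap[lcm_t].max()
        if d_lcm > d_gcm:
            # modal interval ends at the rightmost lcm touch point attaining
            # the max gap; it starts at the gcm touch point just left of it
            d = d_lcm
            right = int(lcm_t[np.flatnonzero(gap[lcm_t] == d_lcm)[-1]])
            left_candidates = gcm_t[gcm_t <= right]
            left = int(left_candidates[-1]) if left_candidates.size else 0
        else:
            d = d_gcm
            left = int(gcm_t[np.flatnonzero(gap[gcm_t] == d_gcm)[0]])
            right_candidates = lcm_t[lcm_t >= left]
            right = int(right_candidates[0]) if right_candidates.size else k - 1

        # sup deviation of the empirical CDF from the hulls on the pieces
        # outside the candidate modal interval.  The modal-interval endpoints
        # themselves are excluded: deviations there are covered by the
        # gcm-lcm gap (and the fitted CDF may carry an atom at the mode).
        dev_left = np.abs(gcm[:left] - yr[:left]).max() if left > 0 else 0.0
        dev_right = (
            np.abs(lcm[right + 1 :] - yl[right + 1 :]).max() if right < k - 1 else 0.0
        )

        if d <= best or (left == 0 and right == k - 1) or left >= right:
            return float(max(best, dev_left, dev_right) / 2.0)
        best = max(best, dev_left, dev_right)
        lo, hi = lo + left, lo + right


_NULL_TABLE_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _null_dips(n: int, n_boot: int, seed: int) -> np.ndarray:
    """Dips of ``n_boot`` uniform(0, 1) samples of size ``n`` (cached)."""
    key = (n, n_boot, seed)
    table = _NULL_TABLE_CACHE.get(key)
    if table is None:
        rng = np.random.default_rng(seed)
        table = np.sort([dip_statistic(rng.random(n)) for _ in range(n_boot)])
        _NULL_TABLE_CACHE[key] = table
    return table


def dip_pvalue(dip: float, n: int, n_boot: int = 999, seed: int = 0) -> float:
    """Bootstrap p-value of an observed dip under the uniform null.

    p = (k + 1) / (n_boot + 1) where k counts null dips >= the observed dip
    (add-one correction, so p is never exactly 0).
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200 for a stable p-value")
    table = _null_dips(int(n), int(n_boot), int(seed))
    k = int(np.sum(table >= dip))
    return (k + 1) / (n_boot + 1)


def skewness_type1(values) -> float:
    """Moment coefficient of skewness g1 = m3 / m2^(3/2), no bias correction."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 3:
        raise DegenerateSampleError("skewness requires at least 3 values")
    if np.var(v) == 0:
        raise DegenerateSampleError("skewness undefined for zero-variance sample")
    return float(stats.skew(v, bias=True))


def classify(
    values,
    dip_cut: float = 0.01,
    p_cut: float = 0.05,
    skew_cut: float = 0.5,
    n_boot: int = 999,
    seed: int = 0,
    case: str = "total",
) -> ClassificationResult:
    """Assign a topography class to one elevation-value set.

    An empty value set is legal only for the intact case and yields the
    ``intensified`` class (no intact land remains).  The bootstrap p-value is
    only computed when the dip exceeds ``dip_cut`` — below it the class does
    not depend on p (the value 1.0 is recorded then).

    Boundary semantics follow the printed rules exactly: ``dip > dip_cut``
    strict, ``|g1| >= skew_cut`` inclusive.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        if case != "intact":
            raise DegenerateSampleError(
                "a mountain range must have elevation values in the total case"
            )
        return ClassificationResult(
            dip=float("nan"),
            dip_p=float("nan"),
            skewness=float("nan"),
            mclass=MountainClass.INTENSIFIED,
            n=0,
            case=case,
        )
    if v.size < 4 or np.var(v) == 0:
        # Too few cells (or a flat remnant) to support the dip/skew screens;
        # such slivers fall through to the remainder class.
        warnings.warn(
            f"{case} sample of size {v.size} too degenerate to classify; "
            "assigning the remainder (diamond) class",
            stacklevel=2,
        )
        return ClassificationResult(
            dip=float("nan"),
            dip_p=float("nan"),
            skewness=float("nan"),
            mclass=MountainClass.DIAMOND,
            n=int(v.size),
            case=case,
        )

    dip = dip_statistic(v)
    if dip > dip_cut:
        p = dip_pvalue(dip, n=v.size, n_boot=n_boot, seed=seed)
    else:
        p = 1.0
    g1 = skewness_type1(v)

    if dip > dip_cut and p < p_cut:
        mclass = MountainClass.HOURGLASS
    elif g1 >= skew_cut:
        mclass = MountainClass.PYRAMID
    elif g1 <= -skew_cut:
        mclass = MountainClass.INVERSE_PYRAMID
    else:
        mclass = MountainClass.DIAMOND
    return ClassificationResult(
        dip=dip, dip_p=p, skewness=g1, mclass=mclass, n=int(v.size), case=case
    )
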
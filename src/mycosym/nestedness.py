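"""Nestedness statistics (NODF, matrix temperature T, discrepancy BR)
with CE null-model significance.

Nestedness is the tendency of specialists' partners to be subsets of
generalists' partners.  Three classical statistics are provided:

* ``nodf`` — overlap-and-decreasing-fill average over all row and column
  pairs (0-100, higher = more nested);
* ``temperature`` — departure from the isocline of perfect nestedness
  (0 deg = perfectly nested, 100 deg = maximally "unexpected");
* ``br_discrepancy`` — number of presences that would have to move to make
  each row a perfect left-packed prefix (0 = perfectly nested).

Significance uses the CE (null model 2) ensemble: each cell is an
independent Bernoulli draw with probability equal to the mean of its row
fill and column fill.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .incidence import IncidenceMatrix, pack

logger = logging.getLogger(__name__)

__all__ = [
    "NestednessResult",
    "NullEnsemble",
    "nodf",
    "temperature",
    "br_discrepancy",
    "ce_null",
    "nestedness_significance",
    "NESTEDNESS_METRICS",
]

#: metric name -> (callable on binary array, direction: +1 if larger = more nested)
NESTEDNESS_METRICS = {}


def _as_array(mat) -> np.ndarray:
    M = mat.M if isinstance(mat, IncidenceMatrix) else np.asarray(mat, dtype=int)
    if M.size == 0:
        raise ValueError("empty matrix")
    return M


@dataclass
class NestednessResult:
    metric: str
    observed: float
    null_mean: float | None
    null_sd: float | None
    z: float | None
    p: float | None
    n_replicates: int
    nested: bool | None = None
    seed: int | None = None


@dataclass
class NullEnsemble:
    generator: str
    values: np.ndarray  # metric value per replicate
    seed: int | None
    n_redraws: int = 0


# ---------------------------------------------------------------------------
# NODF


def nodf(mat):
    """NODF over rows, columns, and the full matrix.

    For an ordered pair (u, l) with ``total(u) > total(l)`` the paired term is
    ``100 * |shared partners| / total(l)``; pairs without decreasing fill
    contribute 0.  Returns ``(NODF_full, NODF_rows, NODF_cols)``; a component
    with a single row/column is undefined and reported as ``nan``.
    """
    M = _as_array(mat)

    def pairs_sum(A):
        # A: rows are the compared axis; pairwise overlaps via A @ A.T
        tot = A.sum(axis=1)
        n = A.shape[0]
        shared = A @ A.T
        hi = np.maximum.outer(tot, tot)
        lo = np.minimum.outer(tot, tot)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where((hi > lo) & (lo > 0), 100.0 * shared / lo, 0.0)
        iu = np.triu_indices(n, k=1)
        return term[iu].tolist()

    row_terms = pairs_sum(M) if M.shape[0] > 1 else []
    col_terms = pairs_sum(M.T) if M.shape[1] > 1 else []
    nodf_rows = float(np.mean(row_terms)) if row_terms else float("nan")
    nodf_cols = float(np.mean(col_terms)) if col_terms else float("nan")
    all_terms = row_terms + col_terms
    nodf_full = float(np.mean(all_terms)) if all_terms else float("nan")
    return nodf_full, nodf_rows, nodf_cols


# ---------------------------------------------------------------------------
# Matrix temperature


def _isocline_exponent(fill: float) -> float:
    """Shape parameter p of the perfect-nestedness isocline for a given fill.

    The isocline family is y(x) = 1 - (1 - (1-x)^p)^(1/p) on the unit square
    (x along columns, y along rows, origin top-left); p is chosen so the area
    above the isocline equals the matrix fill.
    """

    def area_minus_fill(p):
        val, _ = quad(lambda x: 1.0 - (1.0 - (1.0 - x) ** p) ** (1.0 / p), 0.0, 1.0)
        return val - fill

    lo, hi = 1e-6, 20.0
    flo, fhi = area_minus_fill(lo), area_minus_fill(hi)
    while flo * fhi > 0 and hi < 1e6:
        hi *= 2
        fhi = area_minus_fill(hi)
    return brentq(area_minus_fill, lo, hi)


def _temperature_ordering(M: np.ndarray):
    """Row/column ordering for the temperature calculation.

    Follows the published iterative refinement: each line is scored by the
    squared rank positions of its presences and absences on the other axis,
    and the two axes are re-ranked alternately.  Score ties are broken
    deterministically by first occurrence (the reference program breaks them
    at random, which makes its T vary a little from run to run; here repeated
    calls are bit-identical, and input row/column order can still shift T by
    the same small tie-resolution margin — a property shared by every
    implementation of this construction).
    """
    from scipy.stats import rankdata

    nr, nc = M.shape

    def linepack(X, other_rank):
        # X: lines along axis 0 to be ranked, using ranks of the other axis
        n_other = X.shape[1]
        s = -((X * other_rank) ** 2).sum(axis=1)
        t = -((n_other - (1 - X) * other_rank + 1) ** 2).sum(axis=1)
        return rankdata(s + t, method="ordinal").astype(float)

    if nc >= nr:
        i = rankdata(-M.sum(axis=1), method="average")
        j = None
    else:
        j = rankdata(-M.sum(axis=0), method="average")
        i = linepack(M, j)
    for _ in range(8):
        j = linepack(M.T, i)
        i = linepack(M, j)
    if nc < nr:
        j = linepack(M.T, i)
    return np.argsort(i, kind="stable"), np.argsort(j, kind="stable")


def temperature(mat, packed: bool = False) -> float:
    """Matrix temperature in degrees, 0 (perfectly nested) to 100.

    Each cell is mapped into the unit square; unexpected presences (below the
    isocline) and absences (above it) score the squared relative distance to
    the isocline measured along the cell's +-45 deg diagonal; T is the mean
    unexpectedness scaled by the maximal-unexpectedness calibration constant
    (0.04145) so the maximally surprising matrix scores 100.
    """
    M = _as_array(mat)
    if not packed:
        ri, ci = _temperature_ordering(M)
        M = M[np.ix_(ri, ci)]
    fill = M.sum() / M.size
    if fill in (0.0, 1.0):
        warnings.warn("fully filled or fully empty matrix: temperature is 0 by convention")
        return 0.0
    nr, nc = M.shape
    p = _isocline_exponent(fill)

    def iso(x):
        return 1.0 - (1.0 - (1.0 - x) ** p) ** (1.0 / p)

    r = (np.arange(1, nr + 1) - 0.5) / nr  # row coordinate (top row smallest)
    c = (np.arange(1, nc + 1) - 0.5) / nc
    # crossing point of the isocline with the +-45 deg diagonal through cell
    # (i, j): solve iso(x) - x = c_j - r_i.  g(x) = iso(x) - x is strictly
    # decreasing on [0, 1], so all cells invert one tabulated function.
    xs = np.linspace(0.0, 1.0, 4001)
    g = iso(xs) - xs  # decreasing from 1 to -1
    a = c[None, :] - r[:, None]
    x_cross = np.interp(-a, -g, xs)
    d_total = 1.0 - np.abs(r[:, None] - c[None, :])
    u = (r[:, None] - x_cross) / d_total
    # expected cells contribute nothing: presences above the isocline (u<0),
    # absences below it (u>0)
    u[(u < 0) & (M == 1)] = 0.0
    u[(u > 0) & (M == 0)] = 0.0
    t = 100.0 * float((u**2).sum()) / M.size / 0.04145
    return min(t, 100.0)


# ---------------------------------------------------------------------------
# Brualdi-Sanderson discrepancy


def br_discrepancy(mat, packed: bool = False) -> int:
    """Discrepancy: presences falling outside each row's left-packed prefix.

    After packing, row i with total r_i would ideally fill its leftmost r_i
    columns; BR sums, over rows, the presences outside that prefix (equal to
    the absences inside it).  0 iff the packed matrix is perfectly nested.
    """
    M = _as_array(mat)
    if not packed:
        M = pack(M)
    br = 0
    for row in M:
        r = int(row.sum())
        br += int(row[r:].sum())
    return br


# ---------------------------------------------------------------------------
# CE null model


def ce_probabilities(M: np.ndarray) -> np.ndarray:
    """Cell occupancy probabilities: mean of row fill and column fill."""
    M = np.asarray(M, dtype=float)
    nr, nc = M.shape
    rowfill = M.sum(axis=1, keepdims=True) / nc
    colfill = M.sum(axis=0, keepdims=True) / nr
    return 0.5 * (rowfill + colfill)


def ce_null(mat, n_rep: int = 999, seed=None, metric=None,
            max_redraws_per_rep: int = 30) -> NullEnsemble:
    """CE (null model 2) ensemble of ``n_rep`` Bernoulli replicate matrices.

    Replicates with an all-zero row or column are redrawn (degenerate margins
    leave the metrics undefined), up to ``max_redraws_per_rep`` attempts; for
    sparse matrices a fully non-degenerate draw can be practically
    unreachable, in which case the replicate keeps its last draw and empty
    rows/columns are dropped before the metric is evaluated (mirroring how
    observed incidence matrices discard empty margins).  Redraw and trim
    counts are logged.  If ``metric`` (a callable on a binary array) is
    given, per-replicate metric values are returned; otherwise the replicate
    matrices themselves.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    M = _as_array(mat)
    P = ce_probabilities(M)
    rng = np.random.default_rng(seed)
    out = []
    n_redraws = 0
    n_trimmed = 0
    for _ in range(n_rep):
        for _attempt in range(max_redraws_per_rep + 1):
            R = (rng.random(M.shape) < P).astype(int)
            if R.sum() and R.sum(axis=1).all() and R.sum(axis=0).all():
                break
            n_redraws += 1
        else:
            pass
        if not (R.sum(axis=1).all() and R.sum(axis=0).all()):
            R = R[R.sum(axis=1) > 0][:, R.sum(axis=0) > 0]
            n_trimmed += 1
            if R.size == 0:
                R = np.ones((1, 1), dtype=int)
        out.append(metric(R) if metric is not None else R)
    if n_redraws:
        logger.info(
            "CE null model: %d degenerate redraws, %d replicates trimmed",
            n_redraws, n_trimmed,
        )
    values = (
        np.array(out)
        if metric is not None
        else np.array(out, dtype=object) if n_trimmed else np.array(out, dtype=int)
    )
    return NullEnsemble("CE", values, seed if isinstance(seed, int) else None, n_redraws)


# ---------------------------------------------------------------------------
# Significance

_METRIC_FUNCS = {
    "T": (lambda M: temperature(M), -1),
    "NODF_full": (lambda M: nodf(M)[0], +1),
    "NODF_rows": (lambda M: nodf(M)[1], +1),
    "NODF_cols": (lambda M: nodf(M)[2], +1),
    "BR": (lambda M: br_discrepancy(M), -1),
}
NESTEDNESS_METRICS.update(_METRIC_FUNCS)


def nestedness_significance(mat, metric: str, n_rep: int = 999, seed=None,
                            alpha: float = 0.05) -> NestednessResult:
    """One-sided CE-null test in the direction of greater nestedness.

    For NODF p = (1 + #{null >= obs}) / (n_rep + 1); for T and BR the tail is
    reversed (smaller = more nested).  Z = (obs - null mean)/null sd, reported
    as ``None`` when the null sd is 0.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRIC_FUNCS)}")
    func, direction = _METRIC_FUNCS[metric]
    M = _as_array(mat)
    obs = func(M)
    ens = ce_null(M, n_rep=n_rep, seed=seed, metric=func)
    null = ens.values.astype(float)
    mean, sd = float(null.mean()), float(null.std(ddof=1)) if len(null) > 1 else 0.0
    if direction > 0:
        b = int((null >= obs).sum())
    else:
        b = int((null <= obs).sum())
    p = (1 + b) / (n_rep + 1)
    z = (obs - mean) / sd if sd > 0 else None
    return NestednessResult(
        metric=metric,
        observed=float(obs),
        null_mean=mean,
        null_sd=sd,
        z=z,
        p=p,
        n_replicates=n_rep,
        nested=p <= alpha,
        seed=seed if isinstance(seed, int) else None,
    )
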
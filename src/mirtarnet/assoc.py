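"""Expression-based pairwise association scores.

Three families of scores are provided for miRNA-mRNA pairs observed across
matched samples:

* Pearson / Spearman correlation;
* the Kraskov-Stoegbauer-Grassberger (KSG) k-nearest-neighbour mutual
  information estimator, variant 1, in nats;
* the maximal information coefficient (MIC): mutual information of the best
  p-by-q grid, normalized by ``log2 min(p, q)`` and maximized over all grid
  shapes with ``p * q <= n**alpha``, in [0, 1].

MIC is computed exactly (full enumeration of grid lines between distinct
data values) for every grid shape whose search space is small, and by the
equipartition/clump dynamic program otherwise; at the sample sizes typical
of expression panels every shape falls in the exact regime.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma
from scipy.stats import rankdata

from .data_io import CapabilityError, DataKind, DesignError, ExpressionDataset

logger = logging.getLogger(__name__)

ASSOC_METHODS = ("pearson", "spearman", "mutual_information", "mic")


@dataclass
class ScoreTable:
    """Per-pair association scores for one method."""

    method: str
    rows: pd.DataFrame  # columns: mirna_id, mrna_id, score
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rows.duplicated(subset=["mirna_id", "mrna_id"]).any():
            raise ValueError("duplicate scored pair")
        s = self.rows["score"].to_numpy(dtype=float)
        if self.method == "mic" and len(s) and (s.min() < -1e-9 or s.max() > 1 + 1e-9):
            raise ValueError("mic scores must lie in [0, 1]")
        if self.method in ("pearson", "spearman") and len(s) and np.abs(s).max() > 1 + 1e-9:
            raise ValueError("correlation scores must lie in [-1, 1]")

    def to_tsv(self, path) -> None:
        out = self.rows.copy()
        out.insert(2, "method", self.method)
        out.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.rows)


class ConstantVectorError(ValueError):
    """Correlation is undefined for a constant vector."""


def correlation(x, y, method: str = "pearson") -> float:
    """Product-moment correlation; Spearman ranks both vectors first."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with at least 3 observations")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    if method == "spearman":
        x = rankdata(x)
        y = rankdata(y)
    x = x - x.mean()
    y = y - y.mean()
    return float(np.dot(x, y) / math.sqrt(np.dot(x, x) * np.dot(y, y)))


def _deterministic_jitter(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Break ties with a tiny jitter seeded from the data themselves.

    The KSG estimator assumes continuous marginals; expression values are
    frequently tied.  Magnitude is 1e-10 of the value range so the joint
    ordering of well-separated points is untouched, and the seed is a hash of
    the input so repeated calls agree bit-for-bit.
    """
    digest = hashlib.sha256(np.ascontiguousarray(np.c_[x, y]).tobytes()).digest()
    seed = int.from_bytes(digest[:4], "little")
    rng = np.random.default_rng(seed)
    out = []
    for v in (x, y):
        scale = 1e-10 * (np.ptp(v) if np.ptp(v) > 0 else 1.0)
        out.append(v + rng.uniform(-scale, scale, size=len(v)))
    return out[0], out[1]


def ksg_mutual_information(x, y, k: int = 3) -> float:
    """KSG mutual information estimate (variant 1), in nats.

    For each point the Chebyshev distance to its k-th nearest joint
    neighbour defines a box; ``n_x`` and ``n_y`` count the points strictly
    inside the box marginally.  The estimate is
    ``psi(k) + psi(N) - <psi(n_x+1) + psi(n_y+1)>`` and may be negative for
    weakly dependent data; it is returned unclamped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < N, got k={k}, N={n}")
    if len(np.unique(x)) < n or len(np.unique(y)) < n:
        x, y = _deterministic_jitter(x, y)

    pts = np.c_[x, y]
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k + 1, p=np.inf)
    eps = dist[:, k]

    def marginal_counts(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v)
        vs = v[order]
        hi = np.searchsorted(vs, v + eps, side="left")
        lo = np.searchsorted(vs, v - eps, side="right")
        return hi - lo - 1  # exclude the point itself

    nx = marginal_counts(x)
    ny = marginal_counts(y)
    return float(
        digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    )


# --------------------------------------------------------------------------
# MIC


def _distinct_boundaries(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map values to distinct-value indices; return (codes, counts)."""
    _, codes, counts = np.unique(v, return_inverse=True, return_counts=True)
    return codes, counts


def _grid_information(cells: np.ndarray) -> np.ndarray:
    """Mutual information in bits of count tables; cells shape (..., p, q)."""
    n = cells.sum(axis=(-2, -1), keepdims=True)
    p = cells / n
    px = p.sum(axis=-1, keepdims=True)
    py = p.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * (np.log2(p) - np.log2(px) - np.log2(py))
    return np.nan_to_num(term, nan=0.0, posinf=0.0, neginf=0.0).sum(axis=(-2, -1))


def _exact_shape_max(M: np.ndarray, p: int, q: int, dx: int, dy: int) -> float:
    """Max grid MI (bits) for shape (p columns, q rows) by full enumeration.

    ``M`` is the (dx+1, dy+1) cumulative joint count matrix over distinct
    x / y values; grid lines run between distinct values only, so tied
    values always share a cell.
    """
    xcuts = np.array(list(itertools.combinations(range(1, dx), p - 1)), dtype=int)
    ycuts = np.array(list(itertools.combinations(range(1, dy), q - 1)), dtype=int)
    if len(xcuts) == 0 or len(ycuts) == 0:
        return 0.0
    xb = np.hstack([np.zeros((len(xcuts), 1), int), xcuts, np.full((len(xcuts), 1), dx)])
    yb = np.hstack([np.zeros((len(ycuts), 1), int), ycuts, np.full((len(ycuts), 1), dy)])
    # corner sums at every boundary pair -> cell counts by double differencing
    A = M[xb[:, None, :, None], yb[None, :, None, :]]
    cells = np.diff(np.diff(A, axis=2), axis=3)
    return float(_grid_information(cells).max())


def _equipartition(codes: np.ndarray, counts: np.ndarray, q: int) -> np.ndarray:
    """Assign each distinct value to one of up to q bins of ~equal mass.

    Ties (a distinct value and all its copies) always land in a single bin;
    when a boundary falls inside a run of ties the run goes to the lower bin.
    """
    n = counts.sum()
    bins = np.empty(len(counts), dtype=int)
    b = 0
    filled = 0
    for i, cnt in enumerate(counts):
        remaining_vals = len(counts) - i
        remaining_bins = q - b
        target = (n - filled) / remaining_bins if remaining_bins > 0 else np.inf
        # open a new bin when the current one met its target (keep enough
        # distinct values to populate the remaining bins)
        if filled >= target - 1e-9 and b < q - 1 and remaining_vals >= remaining_bins:
            b += 1
            filled = 0
        bins[i] = b
        filled += cnt
    return bins[codes]


def _dp_shape_max(
    x_codes: np.ndarray,
    row_of_point: np.ndarray,
    p: int,
    q: int,
    c: int,
) -> float:
    """Max grid MI (bits) for up-to-p columns against a fixed row partition.

    Points are collapsed into clumps (maximal x-runs within one row, x-ties
    inseparable), capped at ``c * p`` superclumps, and the optimal column
    boundaries are found by dynamic programming: the objective
    ``H(P) - H(P,Q)`` is additive over columns.
    """
    n = len(x_codes)
    order = np.lexsort((row_of_point, x_codes))
    xs = x_codes[order]
    rs = row_of_point[order]

    # clump boundaries: new clump when row changes across a distinct-x step
    clump_id = np.zeros(n, dtype=int)
    cid = 0
    for i in range(1, n):
        if xs[i] == xs[i - 1]:
            clump_id[i] = cid
            continue
        if rs[i] != rs[i - 1]:
            cid += 1
        clump_id[i] = cid
    # x-tied runs spanning several rows stay merged; ensure monotone ids
    for i in range(1, n):
        if xs[i] == xs[i - 1] and clump_id[i] != clump_id[i - 1]:
            clump_id[i] = clump_id[i - 1]
    clump_id = np.unique(clump_id, return_inverse=True)[1]
    m = clump_id.max() + 1

    max_clumps = max(p, int(c * p))
    if m > max_clumps:  # merge into ~equal-mass superclumps
        csize = np.bincount(clump_id, minlength=m)
        cum = np.cumsum(csize)
        edges = np.searchsorted(cum, np.linspace(0, n, max_clumps + 1)[1:-1])
        super_of = np.zeros(m, dtype=int)
        super_of[np.unique(np.clip(edges + 1, 0, m - 1))] = 1
        super_of = np.cumsum(super_of)
        clump_id = super_of[clump_id]
        clump_id = np.unique(clump_id, return_inverse=True)[1]
        m = clump_id.max() + 1

    # cumulative per-row histograms over clumps
    hist = np.zeros((m + 1, q))
    for cidx, r in zip(clump_id, rs):
        hist[cidx + 1, r] += 1
    cum = np.cumsum(hist, axis=0)  # cum[t] = row histogram of clumps < t

    def column_term(s: int, t: int) -> float:
        nj = cum[t] - cum[s]
        tot = nj.sum()
        pos = nj[nj > 0]
        return float(-(tot / n) * math.log2(tot / n) + np.sum((pos / n) * np.log2(pos / n)))

    # best[t][l]: max sum of column terms over first t clumps in l columns
    neg = -math.inf
    best = np.full((m + 1, p + 1), neg)
    for t in range(1, m + 1):
        best[t, 1] = column_term(0, t)
    for l in range(2, p + 1):
        for t in range(l, m + 1):
            best[t, l] = max(best[s, l - 1] + column_term(s, t) for s in range(l - 1, t))

    py = cum[m] / n
    h_q = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))
    achievable = [best[m, l] for l in range(2, p + 1) if best[m, l] > neg]
    if not achievable:
        return 0.0
    return max(achievable) + h_q


_EXACT_GRID_BUDGET = 2_000_000  # cap on nc * nr * (p+1) * (q+1) cells


def mic(x, y, alpha: float = 0.6, c: int = 15) -> float:
    """Maximal information coefficient of two vectors, in [0, 1].

    Grid shapes (p, q) with ``p * q <= ceil(n**alpha)`` and p, q >= 2 are
    searched; each shape's score is the best grid's mutual information in
    bits over ``log2 min(p, q)``.  ``c`` bounds the clump count (``c * p``)
    in the dynamic-programming search used when a shape is too large to
    enumerate exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if n < 8:
        raise ValueError("mic requires at least 8 observations")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if c < 1:
        raise ValueError("c must be >= 1")

    b_max = int(math.ceil(n**alpha))
    x_codes, x_counts = _distinct_boundaries(x)
    y_codes, y_counts = _distinct_boundaries(y)
    dx, dy = len(x_counts), len(y_counts)
    if dx < 2 or dy < 2:
        return 0.0  # a constant axis admits no informative grid

    # cumulative joint counts over distinct-value boundaries
    M = np.zeros((dx + 1, dy + 1))
    np.add.at(M, (x_codes + 1, y_codes + 1), 1.0)
    M = M.cumsum(axis=0).cumsum(axis=1)

    best = 0.0
    for p in range(2, b_max // 2 + 1):
        for q in range(2, b_max // p + 1):
            norm = math.log2(min(p, q))
            ncomb_x = math.comb(dx - 1, p - 1)
            ncomb_y = math.comb(dy - 1, q - 1)
            cost = ncomb_x * ncomb_y * (p + 1) * (q + 1)
            if cost <= _EXACT_GRID_BUDGET:
                info = _exact_shape_max(M, p, q, dx, dy)
            else:
                rows_y = _equipartition(y_codes, y_counts, q)
                info = _dp_shape_max(x_codes, rows_y, p, q, c)
                rows_x = _equipartition(x_codes, x_counts, p)
                info = max(info, _dp_shape_max(y_codes, rows_x, q, p, c))
            best = max(best, info / norm)
    return min(best, 1.0)


# --------------------------------------------------------------------------
# pairwise scoring


def score_pairs(
    mirna_ds: ExpressionDataset,
    mrna_ds: ExpressionDataset,
    method: str,
    params: Optional[Mapping] = None,
    candidates: Optional[Iterable[tuple[str, str]]] = None,
) -> ScoreTable:
    """Score (miRNA, mRNA) pairs across matched samples.

    All pairs in the Cartesian product of the two datasets' entities are
    scored unless ``candidates`` restricts the set (e.g. to sequence-predicted
    pairs).  Pairs involving a constant vector are skipped for correlation
    with a warning, since their coefficient is undefined.
    """
    if method not in ASSOC_METHODS:
        raise ValueError(f"unknown association method {method!r}")
    for ds in (mirna_ds, mrna_ds):
        if ds.data_kind is DataKind.STATS_ONLY or ds.values is None:
            raise CapabilityError(
                "expression-based prediction is undefined for statistics-only data"
            )
    if mirna_ds.sample_ids != mrna_ds.sample_ids:
        raise DesignError("miRNA and mRNA datasets must share ordered sample ids")
    params = dict(params or {})

    if candidates is None:
        pair_list = [
            (mi, mr) for mi in mirna_ds.entity_ids for mr in mrna_ds.entity_ids
        ]
    else:
        pair_list = list(candidates)
        known_mi = set(mirna_ds.entity_ids)
        known_mr = set(mrna_ds.entity_ids)
        bad = [p for p in pair_list if p[0] not in known_mi or p[1] not in known_mr]
        if bad:
            raise DesignError(f"candidate pair(s) not in datasets: {bad[:5]}")

    mi_index = {e: i for i, e in enumerate(mirna_ds.entity_ids)}
    mr_index = {e: i for i, e in enumerate(mrna_ds.entity_ids)}
    X = mirna_ds.values
    Y = mrna_ds.values

    records = []
    skipped = 0
    if method in ("pearson", "spearman"):
        if method == "spearman":
            X = np.apply_along_axis(rankdata, 1, X)
            Y = np.apply_along_axis(rankdata, 1, Y)
        Xc = X - X.mean(axis=1, keepdims=True)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        xn = np.sqrt((Xc**2).sum(axis=1))
        yn = np.sqrt((Yc**2).sum(axis=1))
        for mi, mr in pair_list:
            i, j = mi_index[mi], mr_index[mr]
            if xn[i] == 0 or yn[j] == 0:
                skipped += 1
                continue
            records.append((mi, mr, float(np.dot(Xc[i], Yc[j]) / (xn[i] * yn[j]))))
    elif method == "mutual_information":
        k = int(params.get("k", 3))
        for mi, mr in pair_list:
            records.append(
                (mi, mr, ksg_mutual_information(X[mi_index[mi]], Y[mr_index[mr]], k=k))
            )
    else:  # mic
        alpha = float(params.get("alpha", 0.6))
        c = int(params.get("c", 15))
        for mi, mr in pair_list:
            records.append(
                (mi, mr, mic(X[mi_index[mi]], Y[mr_index[mr]], alpha=alpha, c=c))
            )
    if skipped:
        logger.warning("skipped %d pairs with a constant vector (undefined score)", skipped)
    rows = pd.DataFrame(records, columns=["mirna_id", "mrna_id", "score"])
    logger.info("scored %d pairs with %s", len(rows), method)
    return ScoreTable(method=method, rows=rows, params=params)
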
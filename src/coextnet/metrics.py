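"""Weighted bipartite network metrics.

Implements the four structural metrics used to compare true, sampled and
model-predicted networks:

* degree distributions per guild (complementary cumulative form),
* weighted nestedness WNODF (overlap with decreasing fill; 0-100),
* network-level specialisation H2' (Shannon-entropy based; 0-1),
* weighted bipartite modularity, maximised by label propagation with
  agglomerative refinement (LPAwb+-style) over Barber's modularity Q.

All metrics drop empty rows/columns first (sampled networks contain species
that were never detected); the number dropped is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import SpeciesMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkMetricsReport",
    "degree_distribution",
    "wnodf",
    "h2prime",
    "modularity_lpawb",
    "barber_modularity",
    "ensemble_metrics",
]


def _as_array(mat) -> np.ndarray:
    w = mat.weights if isinstance(mat, SpeciesMatrix) else np.asarray(mat, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    return np.asarray(w, dtype=float)


def _drop_empty(w: np.ndarray) -> np.ndarray:
    rows = w.any(axis=1)
    cols = w.any(axis=0)
    dropped = (~rows).sum() + (~cols).sum()
    if dropped:
        logger.debug("dropping %d empty rows/columns before metric computation", dropped)
    return w[np.ix_(rows, cols)]


# ---------------------------------------------------------------------------
# degree distribution


def degree_distribution(mat) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Complementary cumulative degree distribution per guild.

    The degree of a species is its number of nonzero interactions.  Returns,
    for each guild (``"rows"`` = plants, ``"cols"`` = animals), the sorted
    unique degrees and P(degree >= d) evaluated at them.
    """
    w = _as_array(mat)
    if w.size == 0:
        raise ValueError("empty matrix")
    out = {}
    for guild, degrees in (("rows", (w > 0).sum(axis=1)), ("cols", (w > 0).sum(axis=0))):
        uniq = np.unique(degrees)
        ccdf = np.array([(degrees >= d).mean() for d in uniq])
        out[guild] = (uniq, ccdf)
    return out


# ---------------------------------------------------------------------------
# WNODF


def wnodf(mat) -> float:
    """Weighted nestedness based on overlap and decreasing fill (0-100).

    Rows and columns are ordered by decreasing marginal totals.  For every
    ordered pair (u above/left of v) whose totals strictly decrease, the
    paired term is 100 x #{cells with 0 < w_v < w_u} / #{nonzero cells of v};
    tied totals contribute zero.  WNODF is the mean over all row pairs and
    all column pairs.
    """
    w = _drop_empty(_as_array(mat))
    if w.shape[0] < 2 or w.shape[1] < 2:
        raise ValueError("WNODF needs >= 2 non-empty rows and columns")
    total = 0.0
    n_pairs = 0
    for axis_mat in (w, w.T):
        m = axis_mat[np.argsort(-axis_mat.sum(axis=1), kind="stable")]
        totals = m.sum(axis=1)
        r = m.shape[0]
        n_pairs += r * (r - 1) // 2
        for v in range(1, r):
            nz_v = m[v] > 0
            fill_v = nz_v.sum()
            upper = m[:v]
            decreasing = totals[:v] > totals[v]
            if not decreasing.any():
                continue
            less = nz_v & (m[v] < upper[decreasing])
            total += 100.0 * less.sum(axis=1).sum() / fill_v
    return total / n_pairs


# ---------------------------------------------------------------------------
# H2'


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _h2_min(pr: np.ndarray, pc: np.ndarray, tol: float = 1e-12) -> float:
    """Entropy of the maximally specialised allocation with fixed margins.

    Greedy packing: repeatedly route the largest remaining row mass to the
    largest remaining column mass.  Ties break on the lowest index.  This is
    the standard heuristic for the entropy lower bound; exact integer
    optimisation is out of scope.
    """
    r = pr.copy()
    c = pc.copy()
    cells = []
    while True:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        m = min(r[i], c[j])
        if m <= tol:
            break
        cells.append(m)
        r[i] -= m
        c[j] -= m
    return _shannon(np.array(cells))


def _h2_max_integer(r: np.ndarray, c: np.ndarray) -> float:
    """Entropy of the best integer-constrained approximation to independence.

    Starts from the floor of the expected frequencies r_i c_j / m and hands
    out the remaining units one at a time to the feasible cell (row and
    column capacity left) with the largest shortfall against expectation.
    This is the standard integer adjustment for the entropy upper bound on a
    discrete interaction matrix.
    """
    m = r.sum()
    exp = np.outer(r, c) / m
    base = np.floor(exp)
    row_rem = r - base.sum(axis=1)
    col_rem = c - base.sum(axis=0)
    diff = exp - base
    while row_rem.sum() > 0.5:
        feasible = (row_rem[:, None] > 0.5) & (col_rem[None, :] > 0.5)
        if not feasible.any():
            break
        d = np.where(feasible, diff, -np.inf)
        i, j = np.unravel_index(int(np.argmax(d)), d.shape)
        base[i, j] += 1
        diff[i, j] -= 1
        row_rem[i] -= 1
        col_rem[j] -= 1
    return _shannon((base / m).ravel())


def h2prime(mat) -> float:
    """Network-level specialisation H2' in [0, 1].

    Standardises the Shannon entropy of the interaction distribution between
    its extremes attainable with the observed marginal totals:
    H2' = (H2max - H2) / (H2max - H2min).  H2min comes from a greedy
    marginal-packing heuristic.  For integer count matrices H2max uses the
    integer-constrained independence allocation (count data cannot spread
    fractional interactions, which matters for sparse networks); otherwise
    it is the entropy of the exact outer-product allocation.
    0 = no specialisation, 1 = perfect specialisation.
    """
    w = _drop_empty(_as_array(mat))
    tot = w.sum()
    if tot <= 0:
        raise ValueError("H2' is undefined for an all-zero matrix")
    p = w / tot
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    h2 = _shannon(p.ravel())
    integer = bool(np.allclose(w, np.round(w), atol=1e-9))
    if integer:
        h2max = _h2_max_integer(np.round(w).sum(axis=1), np.round(w).sum(axis=0))
    else:
        h2max = _shannon(np.outer(pr, pc).ravel())
    h2min = _h2_min(pr, pc)
    if h2max - h2min < 1e-9:
        return 0.0
    return float(np.clip((h2max - h2) / (h2max - h2min), 0.0, 1.0))


# ---------------------------------------------------------------------------
# weighted bipartite modularity (Barber's Q, LPAwb+-style maximisation)


def barber_modularity(w: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray) -> float:
    """Barber's weighted bipartite modularity Q for a given partition."""
    w = np.asarray(w, dtype=float)
    F = w.sum()
    B = w - np.outer(w.sum(axis=1), w.sum(axis=0)) / F
    same = row_labels[:, None] == col_labels[None, :]
    return float((B * same).sum() / F)


def _propagate(B: np.ndarray, g: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alternate best-label sweeps for columns and rows until stable."""
    R, C = B.shape
    for _ in range(200):
        changed = False
        labels = np.unique(g)
        # column sweep: each column joins the row-module with the largest
        # summed modularity contribution; a fresh label if all are negative
        score = np.vstack([B[g == lab].sum(axis=0) for lab in labels])  # (L, C)
        best = np.argmax(score, axis=0)
        new_h = labels[best]
        fresh = score[best, np.arange(C)] < 0
        if fresh.any():
            free = int(max(g.max(), h.max())) + 1
            new_h = new_h.copy()
            new_h[fresh] = np.arange(free, free + fresh.sum())
        if not np.array_equal(new_h, h):
            h, changed = new_h, True
        # row sweep
        labels = np.unique(h)
        score = np.vstack([B[:, h == lab].sum(axis=1) for lab in labels])  # (L, R)
        best = np.argmax(score, axis=0)
        new_g = labels[best]
        fresh = score[best, np.arange(R)] < 0
        if fresh.any():
            free = int(max(g.max(), h.max())) + 1
            new_g = new_g.copy()
            new_g[fresh] = np.arange(free, free + fresh.sum())
        if not np.array_equal(new_g, g):
            g, changed = new_g, True
        if not changed:
            break
    return g, h


def _agglomerate(B: np.ndarray, g: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy module merging while it raises Q (local maximisation step)."""
    while True:
        labels = np.unique(np.concatenate([g, h]))
        L = labels.size
        if L < 2:
            break
        # gain of merging modules a and b: cross terms between a-rows/b-cols
        # and b-rows/a-cols
        row_in = np.vstack([(g == lab) for lab in labels]).astype(float)  # (L, R)
        col_in = np.vstack([(h == lab) for lab in labels]).astype(float)  # (L, C)
        cross = row_in @ B @ col_in.T  # (L, L): rows of a with cols of b
        gain = cross + cross.T
        np.fill_diagonal(gain, -np.inf)
        a, b = np.unravel_index(np.argmax(gain), gain.shape)
        if gain[a, b] <= 1e-12:
            break
        keep, drop = labels[min(a, b)], labels[max(a, b)]
        g = np.where(g == drop, keep, g)
        h = np.where(h == drop, keep, h)
    return g, h


def modularity_lpawb(mat, n_restarts: int = 20, rng=None) -> tuple[dict, float]:
    """Maximise Barber's weighted bipartite modularity by label propagation.

    Runs ``n_restarts`` label-propagation + agglomeration passes from random
    initial row partitions (plus one deterministic all-singleton start) and
    returns the best partition found.

    Returns
    -------
    (labels, Q) where ``labels`` is ``{"rows": array, "cols": array}`` with
    integer module ids (relabelled 0..M-1) and ``Q`` the modularity.
    """
    rng = np.random.default_rng(rng)
    w = _drop_empty(_as_array(mat))
    if w.sum() <= 0:
        raise ValueError("modularity is undefined for an all-zero matrix")
    R, C = w.shape
    F = w.sum()
    B = w - np.outer(w.sum(axis=1), w.sum(axis=0)) / F

    best_q = -np.inf
    best = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            g = np.arange(R)
        else:
            g = rng.integers(0, rng.integers(1, R + 1), size=R)
        h = np.full(C, -1)
        g, h = _propagate(B, g, h)
        g, h = _agglomerate(B, g, h)
        g, h = _propagate(B, g, h)
        q = float((B * (g[:, None] == h[None, :])).sum() / F)
        if q > best_q + 1e-15:
            best_q, best = q, (g.copy(), h.copy())
    g, h = best
    # relabel modules 0..M-1 in order of first appearance across rows then cols
    order = {lab: i for i, lab in enumerate(dict.fromkeys(np.concatenate([g, h]).tolist()))}
    labels = {
        "rows": np.array([order[x] for x in g]),
        "cols": np.array([order[x] for x in h]),
    }
    return labels, best_q


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class NetworkMetricsReport:
    """Point or ensemble metrics for a network or a set of networks."""

    wnodf: float
    h2prime: float
    modularity_q: float
    module_labels: dict | None = None
    degree_cdf: dict | None = None
    intervals: dict | None = None  # metric -> (lo, hi), ensembles only
    n_networks: int = 1
    n_failed: int = 0


def ensemble_metrics(networks, n_restarts: int = 20, rng=None) -> NetworkMetricsReport:
    """Mean and central 95% interval of each metric over an ensemble.

    The interval convention is conservative for small ensembles: the lower
    bound uses the ``lower`` quantile method and the upper bound ``higher``,
    so two networks yield exactly (min, max).  A network on which a metric
    fails is excluded from that metric with a logged count.
    """
    rng = np.random.default_rng(rng)
    networks = list(networks)
    values: dict[str, list[float]] = {"wnodf": [], "h2prime": [], "modularity_q": []}
    n_failed = 0
    funcs = {
        "wnodf": wnodf,
        "h2prime": h2prime,
        "modularity_q": lambda m: modularity_lpawb(m, n_restarts=n_restarts, rng=rng)[1],
    }
    for net in networks:
        ok = True
        for name, fn in funcs.items():
            try:
                values[name].append(float(fn(net)))
            except ValueError as exc:
                logger.warning("metric %s failed on one network: %s", name, exc)
                ok = False
        if not ok:
            n_failed += 1
    means = {k: float(np.mean(v)) if v else float("nan") for k, v in values.items()}
    intervals = {
        k: (
            float(np.quantile(v, 0.025, method="lower")),
            float(np.quantile(v, 0.975, method="higher")),
        )
        if v
        else (float("nan"), float("nan"))
        for k, v in values.items()
    }
    return NetworkMetricsReport(
        wnodf=means["wnodf"],
        h2prime=means["h2prime"],
        modularity_q=means["modularity_q"],
        intervals=intervals,
        n_networks=len(networks),
        n_failed=n_failed,
    )
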
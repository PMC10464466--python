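"""Data-driven structure exploration for ordinal item pools.

Polychoric correlations (two-step maximum likelihood), ICLUST-style
hierarchical item clustering with iterative removal of poorly fitting
items, exploratory graph analysis (regularized partial-correlation network
with EBIC penalty selection plus walk-based community detection), and
weighted topological overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm

from .itembank import ResponseTable

__all__ = [
    "SimilarityMatrix",
    "polychoric_pair",
    "polychoric",
    "iclust_refine",
    "ClusterTree",
    "ega",
    "CommunitySolution",
    "wto",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# polychoric correlation


def _bvn_rect_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Cell probabilities of a discretized standard bivariate normal.

    tau_x, tau_y: interior thresholds; returns (len+1, len+1) cell matrix.
    """
    tx = np.concatenate([[-np.inf], tau_x, [np.inf]])
    ty = np.concatenate([[-np.inf], tau_y, [np.inf]])
    gx, gy = np.meshgrid(tx, ty, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    finite = np.isfinite(pts).all(axis=1)
    cdf = np.zeros(len(pts))
    # CDF at (-inf, .) or (., -inf) is 0; at (+inf, y) it is Phi(y) etc.
    both_inf_hi = np.isposinf(pts).all(axis=1)
    cdf[both_inf_hi] = 1.0
    x_hi = np.isposinf(pts[:, 0]) & np.isfinite(pts[:, 1])
    cdf[x_hi] = norm.cdf(pts[x_hi, 1])
    y_hi = np.isposinf(pts[:, 1]) & np.isfinite(pts[:, 0])
    cdf[y_hi] = norm.cdf(pts[y_hi, 0])
    if finite.any():
        cdf[finite] = multivariate_normal.cdf(
            pts[finite], mean=[0, 0], cov=[[1, rho], [rho, 1]],
            lower_limit=None,
        )
    F = cdf.reshape(len(tx), len(ty))
    cells = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(cells, 1e-12, 1.0)


def polychoric_pair(table: np.ndarray) -> float:
    """Two-step ML polychoric correlation from a joint contingency table.

    Thresholds come from the univariate margins (inverse-normal cumulative
    proportions); rho maximizes the bivariate-normal contingency likelihood.
    """
    table = np.asarray(table, float)
    n = table.sum()
    px = table.sum(axis=1) / n
    py = table.sum(axis=0) / n
    if (px > 0).sum() < 2 or (py > 0).sum() < 2:
        raise ValueError("degenerate margin: fewer than 2 observed categories")
    tau_x = norm.ppf(np.clip(np.cumsum(px)[:-1], 1e-10, 1 - 1e-10))
    tau_y = norm.ppf(np.clip(np.cumsum(py)[:-1], 1e-10, 1 - 1e-10))

    def nll(rho):
        return -(table * np.log(_bvn_rect_probs(tau_x, tau_y, rho))).sum()

    res = minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-5})
    return float(res.x)


@dataclass
class SimilarityMatrix:
    """Symmetric item similarity (polychoric or Pearson) with pairwise n."""

    values: pd.DataFrame
    pairwise_n: pd.DataFrame
    kind: str = "polychoric"

    @property
    def items(self) -> list:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(float)

    def drop(self, items: Sequence[str]) -> "SimilarityMatrix":
        keep = [i for i in self.items if i not in set(items)]
        return SimilarityMatrix(self.values.loc[keep, keep],
                                self.pairwise_n.loc[keep, keep], self.kind)


def polychoric(
    data: ResponseTable,
    min_pair_n: int = 30,
    method: str = "polychoric",
) -> SimilarityMatrix:
    """Pairwise polychoric (or Pearson) correlation matrix of a response table.

    Pairs with fewer than ``min_pair_n`` joint observations, or with a
    degenerate margin, get NaN entries (logged).
    """
    items = data.items
    arr = data.data.to_numpy(float)
    p = len(items)
    r = np.eye(p)
    npair = np.zeros((p, p), int)
    np.fill_diagonal(npair, (~np.isnan(arr)).sum(axis=0))
    kmax = int(max(data.n_categories.get(i, 5) for i in items)) if items else 5
    for i in range(p):
        for j in range(i + 1, p):
            joint = ~np.isnan(arr[:, i]) & ~np.isnan(arr[:, j])
            nj = int(joint.sum())
            npair[i, j] = npair[j, i] = nj
            if nj < min_pair_n:
                log.info("pair (%s, %s): only %d joint observations; skipped",
                         items[i], items[j], nj)
                r[i, j] = r[j, i] = np.nan
                continue
            xi = arr[joint, i].astype(int) - 1
            xj = arr[joint, j].astype(int) - 1
            if method == "pearson":
                r[i, j] = r[j, i] = float(np.corrcoef(xi, xj)[0, 1])
                continue
            tab = np.zeros((kmax, kmax))
            np.add.at(tab, (xi, xj), 1.0)
            tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
            if min(tab.shape) < 2:
                log.info("pair (%s, %s): degenerate margin; skipped",
                         items[i], items[j])
                r[i, j] = r[j, i] = np.nan
                continue
            r[i, j] = r[j, i] = polychoric_pair(tab)
    idx = pd.Index(items)
    return SimilarityMatrix(pd.DataFrame(r, index=idx, columns=idx),
                            pd.DataFrame(npair, index=idx, columns=idx),
                            kind=method)


# ---------------------------------------------------------------------------
# ICLUST-style hierarchical clustering with iterative item removal


@dataclass
class ClusterTree:
    """Merge history: list of (left, right, beta_merged, alpha_merged)."""

    merges: list = field(default_factory=list)
    clusters: dict = field(default_factory=dict)  # label -> list of items


def _alpha(R: np.ndarray, idx: Sequence[int]) -> float:
    k = len(idx)
    if k < 2:
        return np.nan
    sub = R[np.ix_(idx, idx)]
    total = sub.sum()
    return (k / (k - 1)) * (1 - k / total) if total > 0 else -np.inf


def _beta_merge(R: np.ndarray, a: Sequence[int], b: Sequence[int]) -> float:
    """Worst-split (the split being the merge itself) reliability of A+B.

    beta = 4 cov(A_sum, B_sum) / var(A_sum + B_sum) with unit-variance items.
    """
    va = R[np.ix_(a, a)].sum()
    vb = R[np.ix_(b, b)].sum()
    cab = R[np.ix_(a, b)].sum()
    vtot = va + vb + 2 * cab
    return 4 * cab / vtot if vtot > 0 else -np.inf


def _cluster_loading(R: np.ndarray, i: int, members: Sequence[int]) -> float:
    """Correlation of item i with the unit-weight composite of ``members``."""
    vc = R[np.ix_(members, members)].sum()
    cov = R[i, members].sum()
    return cov / np.sqrt(vc) if vc > 0 else 0.0


def _iclust_once(R: np.ndarray, items: list):
    """One ICLUST pass: agglomerate while merges do not hurt alpha AND beta."""
    clusters = {i: [i] for i in range(len(items))}
    stats = {i: (np.nan, np.nan) for i in clusters}  # (alpha, beta)
    tree = ClusterTree()
    frozen: set = set()
    while True:
        labels = [c for c in clusters if c not in frozen]
        best = None
        for ai in range(len(labels)):
            for bi in range(ai + 1, len(labels)):
                a, b = labels[ai], labels[bi]
                bm = _beta_merge(R, clusters[a], clusters[b])
                if best is None or bm > best[0]:
                    best = (bm, a, b)
        if best is None or len(labels) < 2:
            break
        bm, a, b = best
        merged = clusters[a] + clusters[b]
        am = _alpha(R, merged)
        # stop rule: reject a merge of two multi-item clusters when it
        # decreases both alpha and beta (singletons may always join; weak
        # ones are caught by the loading cut afterwards)
        both_multi = len(clusters[a]) > 1 and len(clusters[b]) > 1
        prev_beta = [stats[c][1] for c in (a, b) if not np.isnan(stats[c][1])]
        prev_alpha = [stats[c][0] for c in (a, b) if not np.isnan(stats[c][0])]
        if both_multi and prev_beta and prev_alpha \
                and bm < min(prev_beta) and am < min(prev_alpha):
            frozen.add(a)
            frozen.add(b)
            continue
        new = max(clusters) + 1
        clusters[new] = sorted(merged)
        stats[new] = (am, bm)
        tree.merges.append((sorted(clusters[a]), sorted(clusters[b]), bm, am))
        del clusters[a], clusters[b]
    tree.clusters = {c: [items[i] for i in mem] for c, mem in clusters.items()}
    return clusters, tree


def iclust_refine(
    sim: SimilarityMatrix,
    loading_cut: float = 0.30,
    max_rounds: int = 25,
):
    """Iterative ICLUST refinement: cluster, drop weak items, repeat.

    Items whose correlation with their assigned cluster composite falls
    below ``loading_cut``, or that end as singletons, are removed each
    round; iteration stops at a stable solution. Ties break toward the
    lexicographically smallest item_id (removal order is sorted).

    Returns (retained_items, ClusterTree, removal_log).
    """
    items = list(sim.items)
    if len(items) < 3:
        raise ValueError("ICLUST refinement needs at least 3 items")
    removal_log = []
    for _ in range(max_rounds):
        R = sim.values.loc[items, items].to_numpy(float)
        R = np.where(np.isnan(R), 0.0, R)
        clusters, tree = _iclust_once(R, items)
        to_remove = []
        for c, mem in clusters.items():
            if len(mem) == 1:
                to_remove.append((items[mem[0]], "singleton"))
                continue
            for i in mem:
                ld = _cluster_loading(R, i, mem)
                if ld < loading_cut:
                    to_remove.append((items[i], f"loading {ld:.3f} < {loading_cut}"))
        if not to_remove:
            return items, tree, removal_log
        to_remove.sort()
        removal_log.extend(to_remove)
        items = [i for i in items if i not in {t[0] for t in to_remove}]
        if len(items) == 0:
            raise ValueError(f"all items removed; log: {removal_log}")
        if len(items) < 3:
            # too few left to cluster further; return what survives
            return items, tree, removal_log
    return items, tree, removal_log


# ---------------------------------------------------------------------------
# exploratory graph analysis


@dataclass
class CommunitySolution:
    """Item communities from a regularized partial-correlation network."""

    membership: dict  # item_id -> community label (contiguous ints from 0)
    network: pd.DataFrame  # signed partial-correlation edge weights
    modularity: float
    alpha: float  # selected glasso penalty

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


def _nearest_pd(m: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh((m + m.T) / 2)
    if vals.min() > eps:
        return m
    log.info("similarity matrix not positive definite; eigenvalue repair applied")
    vals = np.clip(vals, eps, None)
    out = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def ega(
    data: ResponseTable,
    min_pair_n: int = 30,
    n_alphas: int = 100,
    ebic_gamma: float = 0.5,
    method: str = "polychoric",
) -> CommunitySolution:
    """Exploratory graph analysis.

    Estimates a graphical-lasso partial-correlation network on the
    (smoothed) polychoric matrix with EBIC model selection over a
    log-spaced penalty grid, then detects communities with the
    (deterministic) walktrap algorithm on absolute edge weights.
    """
    from sklearn.covariance import graphical_lasso

    sim = polychoric(data, min_pair_n=min_pair_n, method=method)
    items = sim.items
    p = len(items)
    S = sim.to_numpy()
    S = np.where(np.isnan(S), 0.0, S)
    S = _nearest_pd(S)
    n = int(np.median(sim.pairwise_n.to_numpy()[np.triu_indices(p, 1)])) if p > 1 else len(data.data)

    alphas = np.logspace(-3, 0, n_alphas)
    best = None
    for alpha in alphas:
        try:
            _, prec = graphical_lasso(S, alpha=alpha, max_iter=200)
        except Exception:
            continue
        # Gaussian log-likelihood and EBIC
        sign, logdet = np.linalg.slogdet(prec)
        if sign <= 0:
            continue
        ll = n / 2 * (logdet - np.trace(S @ prec))
        off = prec[np.triu_indices(p, 1)]
        E = int((np.abs(off) > 1e-8).sum())
        ebic = -2 * ll + E * np.log(n) + 4 * ebic_gamma * E * np.log(p)
        if best is None or ebic < best[0]:
            best = (ebic, alpha, prec)
    if best is None:
        raise RuntimeError("graphical lasso failed on the whole penalty grid")
    _, alpha, prec = best
    d = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    pcor[np.abs(pcor) < 1e-8] = 0.0

    import igraph as ig

    g = ig.Graph.Weighted_Adjacency(np.abs(pcor).tolist(), mode="undirected",
                                    attr="weight", loops=False)
    if g.ecount() == 0:
        membership = [0] * p
        mod = 0.0
    else:
        dend = g.community_walktrap(weights="weight", steps=4)
        clusts = dend.as_clustering()
        membership = clusts.membership
        mod = float(clusts.modularity)
    # contiguous relabeling in first-appearance order
    relabel: dict = {}
    for m in membership:
        if m not in relabel:
            relabel[m] = len(relabel)
    net = pd.DataFrame(pcor, index=pd.Index(items), columns=pd.Index(items))
    return CommunitySolution(
        {it: relabel[m] for it, m in zip(items, membership)}, net, mod, float(alpha)
    )


# ---------------------------------------------------------------------------
# weighted topological overlap


def wto(weights: pd.DataFrame | np.ndarray, i, j) -> float:
    """Weighted topological overlap of nodes i and j.

    wTO_ij = (sum_u |w_iu w_ju| + |w_ij|) / (min(k_i, k_j) + 1 - |w_ij|)
    with k_i = sum_u |w_iu| (u ranging over all other nodes).
    """
    if isinstance(weights, pd.DataFrame):
        W = weights.to_numpy(float)
        names = list(weights.columns)
        ii, jj = names.index(i), names.index(j)
    else:
        W = np.asarray(weights, float)
        ii, jj = int(i), int(j)
    if ii == jj:
        raise ValueError("wTO is undefined for i == j")
    A = np.abs(W.copy())
    np.fill_diagonal(A, 0.0)
    others = [u for u in range(A.shape[0]) if u not in (ii, jj)]
    num = (A[ii, others] * A[jj, others]).sum() + A[ii, jj]
    ki = A[ii].sum()
    kj = A[jj].sum()
    den = min(ki, kj) + 1 - A[ii, jj]
    return float(num / den)
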
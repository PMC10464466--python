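"""Graded response model (GRM) estimation by marginal maximum likelihood.

Supports unidimensional and confirmatory bifactor structures with
orthogonal factors (variances fixed to 1). Estimation is EM: the E-step
computes posterior weights of each subject over a Gauss–Hermite quadrature
grid; the M-step refits each item's slope(s) and ordered thresholds by
weighted ordinal regression with analytic gradients. Bifactor models use
dimension reduction — because items of different specific factors are
conditionally independent given the general trait, the marginal likelihood
integrates over (general x one specific) two-dimensional grids per item
block rather than the full (1 + S)-dimensional cube.

The probit link is used internally; logit-metric slopes are accepted and
converted with the conventional scaling constant D = 1.702. Under probit,
standardized loadings are lam = a / sqrt(1 + sum a^2), which makes the
linear factor-analytic index formulas exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr  # fast standard normal CDF
from scipy.stats import norm

from .indices import LoadingMatrix
from .itembank import ResponseTable

__all__ = [
    "GRMModel",
    "ScoreSet",
    "PlausibleValueSet",
    "fit_grm",
    "grm_loglik",
    "standardize_loadings",
    "slopes_from_loadings",
    "eap_scores",
    "plausible_values",
    "gauss_hermite",
]

_D = 1.702
_PMIN = 1e-300


def gauss_hermite(n: int = 21):
    """Gauss–Hermite nodes/weights for expectations under N(0, 1)."""
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return x, w / w.sum()


def _cat_probs(lin: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """P(Y = k | linear predictor) for a probit GRM.

    lin: (...,) linear predictor a'theta; thresholds: (K-1,) increasing.
    Returns (..., K).
    """
    z = lin[..., None] - thresholds  # (..., K-1)
    c = ndtr(z)
    first = 1.0 - c[..., :1]
    last = c[..., -1:]
    if thresholds.size > 1:
        mid = c[..., :-1] - c[..., 1:]
        p = np.concatenate([first, mid, last], axis=-1)
    else:
        p = np.concatenate([first, last], axis=-1)
    return np.clip(p, _PMIN, 1.0)


@dataclass
class GRMModel:
    """A fitted (or specified) unidimensional / bifactor probit GRM.

    ``subscale[i]`` is the specific-factor label of item i (None = loads on
    the general factor only); a model with no labels at all is
    unidimensional. Thresholds are in the theta metric (slope-intercept
    form P(Y > k) = Phi(a'theta - b_k)).
    """

    item_ids: list
    a_general: np.ndarray
    a_specific: np.ndarray
    thresholds: list  # list of (K_i - 1,) increasing arrays
    subscale: list
    link: str = "probit"
    n_quad: int = 21
    loglik: float = np.nan
    converged: bool = False
    n_iter: int = 0
    category_remaps: dict = field(default_factory=dict)

    def __post_init__(self):
        self.a_general = np.asarray(self.a_general, float)
        self.a_specific = np.asarray(self.a_specific, float)
        self.thresholds = [np.asarray(t, float) for t in self.thresholds]
        for iid, t in zip(self.item_ids, self.thresholds):
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"item {iid}: thresholds not strictly increasing")
        for i, s in enumerate(self.subscale):
            if s is None and self.a_specific[i] != 0:
                raise ValueError(f"item {self.item_ids[i]}: specific slope without subscale")

    @property
    def subscales(self) -> list:
        seen = []
        for s in self.subscale:
            if s is not None and s not in seen:
                seen.append(s)
        return seen

    @property
    def is_bifactor(self) -> bool:
        return len(self.subscales) > 0

    @property
    def trait_names(self) -> list:
        return ["theta_g"] + [f"theta_{s}" for s in self.subscales]

    def n_free_params(self) -> int:
        n = 0
        for i in range(len(self.item_ids)):
            n += 1 + (self.subscale[i] is not None) + self.thresholds[i].size
        return n

    # -- serialization ------------------------------------------------------
    def to_json(self, path=None) -> str:
        obj = {
            "item_ids": self.item_ids,
            "a_general": self.a_general.tolist(),
            "a_specific": self.a_specific.tolist(),
            "thresholds": [t.tolist() for t in self.thresholds],
            "subscale": self.subscale,
            "link": self.link,
            "n_quad": self.n_quad,
            "loglik": None if np.isnan(self.loglik) else self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "category_remaps": {k: list(v) for k, v in self.category_remaps.items()},
        }
        s = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, src) -> "GRMModel":
        if isinstance(src, (str, bytes)) and not str(src).lstrip().startswith("{"):
            with open(src) as fh:
                obj = json.load(fh)
        else:
            obj = json.loads(src)
        obj["loglik"] = np.nan if obj.get("loglik") is None else obj["loglik"]
        obj["category_remaps"] = {k: tuple(v) for k, v in obj.get("category_remaps", {}).items()}
        return cls(**obj)


# ---------------------------------------------------------------------------
# data preparation


def _encode(data: ResponseTable, item_ids: Sequence[str]):
    """Responses as int codes 0..K-1, -1 missing; returns (codes, K per item)."""
    arr = data.data[list(item_ids)].to_numpy(float)
    codes = np.where(np.isnan(arr), -1, arr - 1).astype(int)
    ks = [data.n_categories.get(i, 5) for i in item_ids]
    return codes, ks


def _collapse_empty(codes: np.ndarray, ks: Sequence[int], item_ids):
    """Collapse unobserved categories into the adjacent lower (or upper) one.

    Returns recoded data, per-item observed category counts, and a remap
    record {item_id: tuple(original_category -> new_code)}.
    """
    out = codes.copy()
    k_obs, remaps = [], {}
    for j, (k, iid) in enumerate(zip(ks, item_ids)):
        col = codes[:, j]
        observed = np.zeros(k, bool)
        observed[col[col >= 0]] = True
        if observed.sum() < 2:
            raise ValueError(
                f"item {iid!r}: fewer than 2 observed categories; cannot estimate"
            )
        newcode = np.cumsum(observed) - 1  # map original cat -> contiguous code
        newcode[~observed] = np.maximum(newcode[~observed], 0)
        out[col >= 0, j] = newcode[col[col >= 0]]
        k_obs.append(int(observed.sum()))
        if not observed.all():
            remaps[iid] = tuple(int(c) for c in newcode)
    return out, k_obs, remaps


# ---------------------------------------------------------------------------
# E-step machinery (shared by loglik, fitting, scoring)


class _Grids:
    def __init__(self, model: GRMModel):
        self.x, self.w = gauss_hermite(model.n_quad)
        self.Q = model.n_quad

    def item_tables(self, model: GRMModel):
        """Per-item category probability tables on the relevant grid.

        General-only items: (Q, K). Block items: (Q, Q, K) over
        (theta_g, theta_s).
        """
        tabs = []
        for i in range(len(model.item_ids)):
            ag = model.a_general[i] * (1 if model.link == "probit" else 1 / _D)
            asp = model.a_specific[i] * (1 if model.link == "probit" else 1 / _D)
            thr = model.thresholds[i] * (1 if model.link == "probit" else 1 / _D)
            if model.subscale[i] is None:
                lin = ag * self.x
                tabs.append(_cat_probs(lin, thr))
            else:
                lin = ag * self.x[:, None] + asp * self.x[None, :]
                tabs.append(_cat_probs(lin, thr))
        return tabs


def _estep(model: GRMModel, codes: np.ndarray, tabs, grids: _Grids,
           want_posteriors: bool = False):
    """Dimension-reduced marginal likelihood pieces.

    Returns (loglik, L_q, blocks) where L_q is the (n, Q) unnormalized
    posterior over the general grid (including prior weights) and blocks
    maps subscale -> (item_indices, M) with M the (n, Q, Q) within-block
    joint conditional likelihood (no prior weights on the specific axis).
    """
    n = codes.shape[0]
    Q = grids.Q
    w = grids.w
    subs = model.subscales
    members = {s: [i for i, lab in enumerate(model.subscale) if lab == s] for s in subs}
    gen_only = [i for i, lab in enumerate(model.subscale) if lab is None]

    logL = np.zeros((n, Q))
    for i in gen_only:
        y = codes[:, i]
        obs = y >= 0
        if obs.any():
            logL[obs] += np.log(tabs[i][:, y[obs]].T)

    blocks = {}
    for s in subs:
        M = np.ones((n, Q, Q))
        for i in members[s]:
            y = codes[:, i]
            obs = y >= 0
            if obs.any():
                M[obs] *= np.moveaxis(tabs[i][:, :, y[obs]], -1, 0)
        B = M @ w  # (n, Q): integrate specific dimension
        logL += np.log(np.clip(B, _PMIN, None))
        blocks[s] = (members[s], M, B)

    m = logL.max(axis=1, keepdims=True)
    Lq = np.exp(logL - m) * w  # (n, Q) includes prior weight
    marg = Lq.sum(axis=1)
    loglik = float((np.log(marg) + m[:, 0]).sum())
    if not want_posteriors:
        return loglik, None, None, None
    post_g = Lq / marg[:, None]  # posterior over general grid
    return loglik, post_g, blocks, logL


def grm_loglik(model: GRMModel, data: ResponseTable) -> float:
    """Marginal log-likelihood of ``data`` under ``model``.

    Missing responses contribute no factor (ignorable missingness).
    """
    common = [i for i in model.item_ids if i in set(data.items)]
    if not common:
        raise ValueError("model and data share no items")
    sub = data.subset_items(common, drop_empty=False)
    idx = [model.item_ids.index(i) for i in common]
    m = GRMModel(
        item_ids=common,
        a_general=model.a_general[idx],
        a_specific=model.a_specific[idx],
        thresholds=[model.thresholds[i] for i in idx],
        subscale=[model.subscale[i] for i in idx],
        link=model.link,
        n_quad=model.n_quad,
    )
    codes, ks = _encode(sub, common)
    grids = _Grids(m)
    tabs = grids.item_tables(m)
    ll, _, _, _ = _estep(m, codes, tabs, grids)
    return ll


# ---------------------------------------------------------------------------
# M-step: weighted ordinal probit regression per item


def _item_objective(params, theta, counts, k):
    """Negative expected complete-data log-likelihood and gradient.

    theta: (T, d) node coordinates for this item's dimensions;
    counts: (T, K) expected response counts at each node.
    params: [a_1..a_d, t1, d_1..d_{K-2}] with b = cumsum([t1, exp(d)]).
    """
    d = theta.shape[1]
    a = params[:d]
    t1 = params[d]
    if k > 2:
        dd = params[d + 1:]
        b = np.concatenate([[t1], t1 + np.cumsum(np.exp(dd))])
    else:
        b = np.array([t1])
    lin = theta @ a
    z = lin[:, None] - b  # (T, K-1)
    c = ndtr(z)
    phi = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
    first = 1.0 - c[:, :1]
    last = c[:, -1:]
    p = np.concatenate([first, c[:, :-1] - c[:, 1:], last], axis=1) if k > 2 \
        else np.concatenate([first, last], axis=1)
    p = np.clip(p, 1e-12, 1.0)
    f = -(counts * np.log(p)).sum()
    # C_k appears with -1 in P_k and +1 in P_{k+1}; chain rule through
    # C_k = Phi(z_k), z_k = a'theta - b_k
    gC = counts[:, 1:] / p[:, 1:] - counts[:, :-1] / p[:, :-1]  # (T, K-1)
    gz = gC * phi
    grad = np.empty_like(params)
    grad[:d] = -(theta * gz.sum(axis=1, keepdims=True)).sum(axis=0)
    dfdb = gz.sum(axis=0)
    grad[d] = dfdb.sum()
    if k > 2:
        ed = np.exp(dd)
        # b_m = t1 + sum_{j<m} exp(d_j); db_m/dd_j = exp(d_j) for m > j
        grad[d + 1:] = np.array(
            [dfdb[j + 1:].sum() * ed[j] for j in range(k - 2)]
        )
    return f, grad


def _fit_item(theta, counts, k, a0, b0):
    x0 = np.concatenate([np.atleast_1d(a0), [b0[0]],
                         np.log(np.maximum(np.diff(b0), 1e-3)) if k > 2 else []])
    res = minimize(_item_objective, x0, args=(theta, counts, k),
                   jac=True, method="L-BFGS-B",
                   bounds=[(-25, 25)] * theta.shape[1] + [(-25, 25)]
                          + [(-10, 6)] * max(k - 2, 0))
    d = theta.shape[1]
    a = res.x[:d]
    t1 = res.x[d]
    b = np.concatenate([[t1], t1 + np.cumsum(np.exp(res.x[d + 1:]))]) if k > 2 \
        else np.array([t1])
    return a, b


# ---------------------------------------------------------------------------
# fitting


def fit_grm(
    data: ResponseTable,
    structure: Mapping[str, str | None] | None = None,
    n_quad: int = 21,
    tol: float = 1e-5,
    max_iter: int = 500,
    min_items: int = 3,
) -> GRMModel:
    """Fit a unidimensional or confirmatory bifactor GRM by EM.

    Parameters
    ----------
    data : ResponseTable
    structure : mapping item_id -> specific-factor label (or None)
        Omitted / all-None = unidimensional. Items absent from the mapping
        load on the general factor only.
    min_items : int
        Unidimensional scales need at least this many items (default 3, the
        requisite minimum for a unidimensional GRM).
    """
    item_ids = list(data.items)
    structure = structure or {}
    subscale = [structure.get(i) for i in item_ids]
    if not any(s is not None for s in subscale) and len(item_ids) < min_items:
        raise ValueError(
            f"{len(item_ids)} items is fewer than the requisite {min_items} "
            "items for a unidimensional GRM"
        )
    if len(item_ids) < 2:
        raise ValueError("need at least 2 items")
    # a specific factor with a single item is unidentified; demote it
    counts_per_sub: dict = {}
    for s in subscale:
        if s is not None:
            counts_per_sub[s] = counts_per_sub.get(s, 0) + 1
    subscale = [None if (s is not None and counts_per_sub[s] < 2) else s
                for s in subscale]

    codes_raw, ks = _encode(data, item_ids)
    codes, k_obs, remaps = _collapse_empty(codes_raw, ks, item_ids)

    # starting values: unit slopes, thresholds from observed margins
    a_g = np.ones(len(item_ids))
    a_s = np.array([1.0 if s is not None else 0.0 for s in subscale])
    thresholds = []
    for j, k in enumerate(k_obs):
        col = codes[:, j]
        col = col[col >= 0]
        cum = np.cumsum(np.bincount(col, minlength=k)[:-1]) / col.size
        cum = np.clip(cum, 1e-3, 1 - 1e-3)
        b = norm.ppf(cum) * np.sqrt(1 + 1 + (subscale[j] is not None))
        b = np.maximum.accumulate(b + 1e-6 * np.arange(k - 1))
        thresholds.append(b)

    model = GRMModel(item_ids, a_g, a_s, thresholds, subscale,
                     link="probit", n_quad=n_quad)
    grids = _Grids(model)
    w = grids.w
    x = grids.x

    last_ll = -np.inf
    history = []
    for it in range(1, max_iter + 1):
        tabs = grids.item_tables(model)
        ll, post_g, blocks, _ = _estep(model, codes, tabs, grids, want_posteriors=True)
        if ll < last_ll - 1e-8 * max(1.0, abs(ll)):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: {last_ll} -> {ll}"
            )
        history.append(ll)
        converged = ll - last_ll < tol and it > 1
        last_ll = ll
        if converged:
            break

        # expected counts and per-item refits
        gen_theta = x[:, None]
        bi_theta = np.column_stack([np.repeat(x, grids.Q), np.tile(x, grids.Q)])
        new_ag = model.a_general.copy()
        new_as = model.a_specific.copy()
        new_thr = [t.copy() for t in model.thresholds]
        # joint posteriors per block
        joint = {}
        for s, (mem, M, B) in blocks.items():
            # post(q, p) = post_g(q) * w_p M(q,p) / B(q)
            joint[s] = post_g[:, :, None] * (M * w[None, None, :]) / \
                np.clip(B, _PMIN, None)[:, :, None]
        for j, iid in enumerate(item_ids):
            k = k_obs[j]
            y = codes[:, j]
            if subscale[j] is None:
                counts = np.zeros((grids.Q, k))
                for c in range(k):
                    sel = y == c
                    if sel.any():
                        counts[:, c] = post_g[sel].sum(axis=0)
                a, b = _fit_item(gen_theta, counts, k,
                                 np.array([model.a_general[j]]),
                                 model.thresholds[j])
                new_ag[j] = a[0]
            else:
                jp = joint[subscale[j]]
                counts = np.zeros((grids.Q * grids.Q, k))
                for c in range(k):
                    sel = y == c
                    if sel.any():
                        counts[:, c] = jp[sel].sum(axis=0).ravel()
                a, b = _fit_item(bi_theta, counts, k,
                                 np.array([model.a_general[j], model.a_specific[j]]),
                                 model.thresholds[j])
                new_ag[j], new_as[j] = a
            new_thr[j] = b
        model = GRMModel(item_ids, new_ag, new_as, new_thr, subscale,
                         link="probit", n_quad=n_quad)

    # reflect factors so each has non-negative loading sum (sign identification)
    if model.a_general.sum() < 0:
        model.a_general = -model.a_general
    for s in model.subscales:
        mem = [i for i, lab in enumerate(model.subscale) if lab == s]
        if model.a_specific[mem].sum() < 0:
            model.a_specific[mem] = -model.a_specific[mem]

    model.loglik = last_ll
    model.converged = converged
    model.n_iter = it
    model.category_remaps = remaps
    model.loglik_history = history  # per-iteration marginal log-likelihood
    return model


# ---------------------------------------------------------------------------
# standardization


def standardize_loadings(model: GRMModel, force: bool = False) -> LoadingMatrix:
    """Standardized loadings lam = a / sqrt(1 + a_G^2 + a_s^2) (probit metric)."""
    if not model.converged and not force:
        raise ValueError("model did not converge; pass force=True to standardize anyway")
    scale = 1.0 if model.link == "probit" else 1.0 / _D
    ag = model.a_general * scale
    asp = model.a_specific * scale
    denom = np.sqrt(1.0 + ag**2 + asp**2)
    return LoadingMatrix(model.item_ids, ag / denom, asp / denom, model.subscale)


def slopes_from_loadings(loadings: LoadingMatrix):
    """Inverse of :func:`standardize_loadings`: (a_general, a_specific) in theta metric."""
    uniq = loadings.uniqueness
    return (loadings.lambda_general / np.sqrt(uniq),
            loadings.lambda_specific / np.sqrt(uniq))


def model_from_spec(spec, n_quad: int = 21) -> GRMModel:
    """GRMModel at the generating parameters of a synthetic BifactorSpec."""
    ag, asp = slopes_from_loadings(spec.loadings)
    thr = [spec.thresholds[i] / np.sqrt(spec.loadings.uniqueness[i])
           for i in range(spec.loadings.n_items)]
    return GRMModel(list(spec.loadings.item_ids), ag, asp, thr,
                    list(spec.loadings.subscale), link="probit", n_quad=n_quad,
                    converged=True)


# ---------------------------------------------------------------------------
# scoring


@dataclass
class ScoreSet:
    """EAP trait estimates with posterior SDs and marginal reliability."""

    eap: "pd.DataFrame"
    psd: "pd.DataFrame"
    marginal_reliability: dict
    all_missing: "pd.Series"


def _posteriors(model: GRMModel, data: ResponseTable):
    common = [i for i in model.item_ids if i in set(data.items)]
    codes, ks = _encode(data, common)
    idx = [model.item_ids.index(i) for i in common]
    m = GRMModel(common, model.a_general[idx], model.a_specific[idx],
                 [model.thresholds[i] for i in idx],
                 [model.subscale[i] for i in idx],
                 link=model.link, n_quad=model.n_quad, converged=True)
    grids = _Grids(m)
    tabs = grids.item_tables(m)
    ll, post_g, blocks, logL = _estep(m, codes, tabs, grids, want_posteriors=True)
    # specific-trait marginal posteriors
    post_s = {}
    for s, (mem, M, B) in blocks.items():
        jp = post_g[:, :, None] * (M * grids.w[None, None, :]) / \
            np.clip(B, _PMIN, None)[:, :, None]
        post_s[s] = jp.sum(axis=1)  # (n, Q) over specific grid
    return m, grids, codes, post_g, post_s, logL


def _conditional_general_posterior(logL, x_nodes, X, n_iter=50, tol=1e-8):
    """Posterior over the general-trait grid under an estimated latent
    regression theta ~ N(X gamma, sigma^2).

    The conditioning model is estimated by EM on the grid; this is the
    secondary-analysis form of the plausible-value framework, which keeps
    regressions of plausible values on the conditioning covariates
    (approximately) unbiased.
    """
    n, Q = logL.shape
    gamma = np.zeros(X.shape[1])
    sigma2 = 1.0
    post = None
    last = None
    XtX_inv = np.linalg.pinv(X.T @ X)
    for _ in range(n_iter):
        mu = X @ gamma
        logpost = logL - 0.5 * (x_nodes[None, :] - mu[:, None]) ** 2 / sigma2
        logpost -= logpost.max(axis=1, keepdims=True)
        post = np.exp(logpost)
        post /= post.sum(axis=1, keepdims=True)
        m1 = post @ x_nodes
        m2 = post @ (x_nodes**2)
        gamma = XtX_inv @ (X.T @ m1)
        fit = X @ gamma
        sigma2 = float(np.mean(m2 - 2 * m1 * fit + fit**2))
        sigma2 = max(sigma2, 1e-4)
        if last is not None and abs(sigma2 - last) < tol:
            break
        last = sigma2
    return post


def eap_scores(model: GRMModel, data: ResponseTable, force: bool = False) -> ScoreSet:
    """EAP estimate and posterior SD per trait; marginal reliability per trait.

    Subjects with no non-missing modeled responses receive the prior
    (mean 0, SD 1) and are flagged.
    """
    if not model.converged and not force:
        raise ValueError("model did not converge; pass force=True to score anyway")
    m, grids, codes, post_g, post_s, _ = _posteriors(model, data)
    x = grids.x
    idx = data.data.index
    all_missing = pd.Series((codes < 0).all(axis=1), index=idx, name="all_missing")

    eap = {}
    psd = {}
    rel = {}
    for name, post in [("theta_g", post_g)] + \
            [(f"theta_{s}", p) for s, p in post_s.items()]:
        mean = post @ x
        var = post @ (x**2) - mean**2
        mean[all_missing.to_numpy()] = 0.0
        var[all_missing.to_numpy()] = 1.0
        eap[name] = mean
        psd[name] = np.sqrt(np.maximum(var, 0.0))
        v_eap = float(np.var(mean))
        rel[name] = v_eap / (v_eap + float(np.mean(var))) if v_eap + np.mean(var) > 0 else 0.0
    return ScoreSet(pd.DataFrame(eap, index=idx), pd.DataFrame(psd, index=idx),
                    rel, all_missing)


@dataclass
class PlausibleValueSet:
    """M posterior draws per subject for one reported trait."""

    trait: str
    draws: "pd.DataFrame"  # columns pv1..pvM
    seed: int

    @property
    def m(self) -> int:
        return self.draws.shape[1]


def plausible_values(
    model: GRMModel,
    data: ResponseTable,
    m: int = 10,
    seed: int = 0,
    trait: str = "theta_g",
    conditioning: "pd.DataFrame | None" = None,
    force: bool = False,
) -> PlausibleValueSet:
    """Draw M plausible values per subject from the quadrature posterior.

    Draws pick a node from the subject's discrete posterior and add uniform
    jitter of half the local node spacing — a reproducible approximation to
    sampling the continuous posterior.

    When ``conditioning`` covariates are supplied (general trait only), the
    posterior is conditioned on an estimated latent regression of the trait
    on those covariates, which keeps secondary-analysis regressions of the
    plausible values unbiased; subjects with missing covariates fall back
    to the unconditional N(0, 1) prior.
    """
    if m < 1:
        raise ValueError("M must be >= 1")
    if not model.converged and not force:
        raise ValueError("model did not converge; pass force=True to draw anyway")
    mm, grids, codes, post_g, post_s, logL = _posteriors(model, data)
    if trait == "theta_g":
        post = post_g
        if conditioning is not None:
            Xdf = conditioning.reindex(data.data.index)
            ok = Xdf.notna().all(axis=1).to_numpy()
            Xc = np.column_stack([np.ones(int(ok.sum())),
                                  Xdf.loc[ok].to_numpy(float)])
            # standardize covariates for a stable latent regression
            mu_x = Xc[:, 1:].mean(axis=0)
            sd_x = Xc[:, 1:].std(axis=0)
            sd_x[sd_x == 0] = 1.0
            Xc[:, 1:] = (Xc[:, 1:] - mu_x) / sd_x
            post = post_g.copy()
            post[ok] = _conditional_general_posterior(logL[ok], grids.x, Xc)
    elif conditioning is not None:
        raise NotImplementedError(
            "conditioned plausible values are only supported for theta_g")
    else:
        key = trait.removeprefix("theta_")
        if key not in post_s:
            raise KeyError(f"trait {trait!r} not in model (have theta_g, "
                           f"{sorted('theta_' + s for s in post_s)})")
        post = post_s[key]
    x = grids.x
    # local half-spacing per node for jitter
    gaps = np.empty_like(x)
    gaps[1:-1] = (x[2:] - x[:-2]) / 2
    gaps[0] = x[1] - x[0]
    gaps[-1] = x[-1] - x[-2]
    rng = np.random.default_rng(seed)
    n = post.shape[0]
    cum = np.cumsum(post, axis=1)
    cum /= cum[:, -1:]
    draws = np.empty((n, m))
    for r in range(m):
        u = rng.random((n, 1))
        node = (u > cum).sum(axis=1)
        jit = rng.uniform(-0.5, 0.5, n) * gaps[node]
        draws[:, r] = x[node] + jit
    cols = [f"pv{r+1}" for r in range(m)]
    return PlausibleValueSet(trait, pd.DataFrame(draws, index=data.data.index,
                                                 columns=cols), seed)
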
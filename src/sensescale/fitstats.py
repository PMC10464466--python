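"""Limited-information global fit assessment for ordinal factor models.

Fit is judged against sample univariate/bivariate margins rather than the
full response-pattern table (which is hopelessly sparse for realistic item
counts). Two complementary statistics are produced:

* SRMR — root mean square difference between sample polychoric
  correlations and the model-implied correlations Lam Lam' (off-diagonal).
* A bivariate-margin chi-square: for every item pair, the Pearson X^2
  between observed joint category proportions and the model-implied joint
  probabilities (integrated over the latent traits), with sparse cells
  pooled to a minimum expected count and the degrees of freedom reduced by
  the number of estimated item parameters. RMSEA and TLI (against an
  independence baseline that fits univariate margins only) are derived
  from this statistic. This is a deliberate, documented approximation to
  published C2-type statistics: the contract is calibration of the a
  priori adequacy gates, not numerical reproduction of any particular
  software's values.

The a priori gates: TLI > 0.97, RMSEA < 0.089, SRMR < 0.05 (0.033 for
3-item composites), marginal reliability rho_xx > 0.7, omega_T > 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .grm import GRMModel, _Grids, _encode, standardize_loadings
from .indices import LoadingMatrix
from .itembank import ResponseTable
from .structure import polychoric

__all__ = ["FitIndexSet", "srmr", "limited_info_chisq", "apply_gates", "GateVerdict"]

MIN_EXPECTED = 1.0


@dataclass
class FitIndexSet:
    """Limited-information fit summary."""

    statistic: float | None
    df: int
    tli: float | None
    rmsea: float | None
    srmr: float
    n: int
    baseline_statistic: float | None = None
    baseline_df: int | None = None

    @property
    def available(self) -> bool:
        return self.statistic is not None and self.df > 0


def srmr_from_matrices(sample: np.ndarray, implied: np.ndarray) -> float:
    """Root mean square of off-diagonal (sample - implied); NaN pairs excluded."""
    sample = np.asarray(sample, float)
    implied = np.asarray(implied, float)
    iu = np.triu_indices(sample.shape[0], 1)
    resid = (sample - implied)[iu]
    ok = ~np.isnan(resid)
    if not ok.any():
        raise ValueError("no estimable item pairs for SRMR")
    return float(np.sqrt(np.mean(resid[ok] ** 2)))


def srmr(loadings: LoadingMatrix, data: ResponseTable, min_pair_n: int = 30) -> float:
    """Limited-information SRMR from polychoric residuals.

    Pairs whose polychoric correlation is unestimable are excluded (logged
    by the polychoric estimator); an error is raised if nothing remains.
    """
    sim = polychoric(data.subset_items(list(loadings.item_ids), drop_empty=False),
                     min_pair_n=min_pair_n)
    sample = sim.values.loc[list(loadings.item_ids), list(loadings.item_ids)].to_numpy()
    return srmr_from_matrices(sample, loadings.implied_correlations())


def _implied_pair_table(model: GRMModel, i: int, j: int, grids: _Grids, tabs) -> np.ndarray:
    """Model-implied joint category probabilities for items i and j."""
    w = grids.w
    si, sj = model.subscale[i], model.subscale[j]
    ti, tj = tabs[i], tabs[j]
    if si is None and sj is None:
        return np.einsum("q,qa,qb->ab", w, ti, tj)
    if si is not None and sj is not None and si == sj:
        return np.einsum("q,p,qpa,qpb->ab", w, w, ti, tj)
    # different (or one missing) specifics: integrate each block separately
    mi = np.einsum("p,qpa->qa", w, ti) if si is not None else ti
    mj = np.einsum("p,qpa->qa", w, tj) if sj is not None else tj
    return np.einsum("q,qa,qb->ab", w, mi, mj)


def _pooled_x2(obs: np.ndarray, exp: np.ndarray, n: int):
    """Pearson X^2 with sparse cells (expected count < MIN_EXPECTED) pooled."""
    o = obs.ravel()
    e = exp.ravel()
    small = e * n < MIN_EXPECTED
    if small.any():
        o = np.append(o[~small], o[small].sum())
        e = np.append(e[~small], e[small].sum())
    e = np.clip(e, 1e-12, None)
    x2 = n * float(((o - e) ** 2 / e).sum())
    return x2, len(o) - 1


def limited_info_chisq(model: GRMModel, data: ResponseTable) -> FitIndexSet:
    """Bivariate-margin chi-square fit statistic with RMSEA/TLI and SRMR.

    RMSEA = sqrt(max(0, (X^2 - df) / (df (N - 1)))); TLI compares the
    statistic-to-df ratio against an independence baseline whose expected
    joint tables are products of observed univariate margins.
    """
    codes, ks = _encode(data, model.item_ids)
    grids = _Grids(model)
    tabs = grids.item_tables(model)
    p = len(model.item_ids)

    x2 = x2_base = 0.0
    cells = cells_base = 0
    n_pairs = 0
    ns = []
    for i in range(p):
        for j in range(i + 1, p):
            joint = (codes[:, i] >= 0) & (codes[:, j] >= 0)
            nij = int(joint.sum())
            if nij < 1:
                continue
            ki, kj = ks[i], ks[j]
            tab = np.zeros((ki, kj))
            np.add.at(tab, (codes[joint, i], codes[joint, j]), 1.0)
            obs = tab / nij
            exp = _implied_pair_table(model, i, j, grids, tabs)
            xx, cc = _pooled_x2(obs, exp, nij)
            x2 += xx
            cells += cc
            mi = obs.sum(axis=1)
            mj = obs.sum(axis=0)
            xb, cb = _pooled_x2(obs, np.outer(mi, mj), nij)
            x2_base += xb
            cells_base += cb
            n_pairs += 1
            ns.append(nij)
    if n_pairs == 0:
        raise ValueError("no jointly observed item pairs")
    n_typ = int(np.mean(ns))

    df = cells - model.n_free_params()
    n_thresh = sum(t.size for t in model.thresholds)
    df_base = cells_base - n_thresh
    s = srmr(standardize_loadings(model, force=True), data)
    if df <= 0:
        return FitIndexSet(None, df, None, None, s, n_typ)
    rmsea = float(np.sqrt(max(0.0, (x2 - df) / (df * (n_typ - 1)))))
    ratio_base = x2_base / max(df_base, 1)
    ratio = x2 / df
    tli = float((ratio_base - ratio) / (ratio_base - 1)) if ratio_base > 1 else 1.0
    return FitIndexSet(x2, df, tli, rmsea, s, n_typ, x2_base, df_base)


@dataclass
class GateVerdict:
    """Pass/fail per a priori criterion; unavailable criteria are recorded."""

    per_criterion: dict = field(default_factory=dict)
    overall: bool = False
    unavailable: list = field(default_factory=list)


def apply_gates(
    fit: FitIndexSet,
    reliability: float | None = None,
    omega_t: float | None = None,
    n_items: int | None = None,
    tli_min: float = 0.97,
    rmsea_max: float = 0.089,
    srmr_max: float = 0.05,
    srmr_max_3item: float = 0.033,
    rel_min: float = 0.70,
) -> GateVerdict:
    """Apply the a priori adequacy gates to a fit summary.

    The SRMR cut tightens to 0.033 for 3-item composites. Criteria whose
    inputs are unavailable (e.g., the chi-square when df <= 0) are skipped
    and listed; the overall verdict is the conjunction of the rest.
    """
    v = GateVerdict()
    srmr_cut = srmr_max_3item if n_items == 3 else srmr_max
    checks = [
        ("tli", fit.tli, lambda x: x > tli_min),
        ("rmsea", fit.rmsea, lambda x: x < rmsea_max),
        ("srmr", fit.srmr, lambda x: x < srmr_cut),
        ("rho_xx", reliability, lambda x: x > rel_min),
        ("omega_t", omega_t, lambda x: x > rel_min),
    ]
    for name, val, ok in checks:
        if val is None:
            v.unavailable.append(name)
        else:
            v.per_criterion[name] = bool(ok(val))
    v.overall = all(v.per_criterion.values()) if v.per_criterion else False
    return v
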
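"""Bifactor model-based reliability and dimensionality indices.

Given a fully standardized bifactor loading matrix (one orthogonal general
factor, each item on at most one orthogonal specific factor), this module
computes the omega family (omega total, omega hierarchical, and their
subscale analogues), explained-common-variance indices (ECV_G, ECV_SS,
within-subscale general ECV, item-level I-ECV), and applies the a priori
decision rules for (a) interpretability of the supra-modal general-factor
score and (b) the added value of modality-specific subscale scores.

All omegas use the linear-composite (unit-weight sum score) formula on
standardized loadings:

    omega_T  = [(sum lam_G)^2 + sum_s (sum_{i in s} lam_s)^2] / V
    omega_H  = (sum lam_G)^2 / V
    V        = (sum lam_G)^2 + sum_s (sum_{i in s} lam_s)^2 + sum_i (1 - h2_i)

with the subscale versions computed over the items of a single subscale
only. ECV indices partition common variance: ECV_G = sum lam_G^2 / sum h2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

__all__ = [
    "LoadingMatrix",
    "BifactorIndexSet",
    "compute_indices",
    "evaluate_interpretability",
    "evaluate_added_value",
]


@dataclass(frozen=True)
class LoadingMatrix:
    """Standardized loadings for a confirmatory bifactor (or 1-factor) model.

    Parameters
    ----------
    item_ids : sequence of str
        Unique item identifiers.
    lambda_general : array-like
        Standardized loading of each item on the general factor.
    lambda_specific : array-like
        Standardized loading on the item's specific factor; 0 (or NaN on
        input) for items loading on the general factor only.
    subscale : sequence of str or None
        Specific-factor label per item; ``None`` for general-only items.
    """

    item_ids: tuple
    lambda_general: np.ndarray
    lambda_specific: np.ndarray
    subscale: tuple

    def __init__(self, item_ids, lambda_general, lambda_specific, subscale):
        item_ids = tuple(str(i) for i in item_ids)
        lg = np.asarray(lambda_general, dtype=float)
        ls = np.asarray(lambda_specific, dtype=float)
        ls = np.where(np.isnan(ls), 0.0, ls)
        sub = tuple(None if (s is None or (isinstance(s, float) and np.isnan(s)) or s == "")
                    else str(s) for s in subscale)
        if not (len(item_ids) == len(lg) == len(ls) == len(sub)):
            raise ValueError("item_ids, loadings and subscale must have equal length")
        if len(set(item_ids)) != len(item_ids):
            raise ValueError("duplicate item_ids in loading matrix")
        for i, s in enumerate(sub):
            if s is None and ls[i] != 0.0:
                raise ValueError(f"item {item_ids[i]}: specific loading without a subscale")
        h2 = lg**2 + ls**2
        if np.any(h2 >= 1.0) or np.any(h2 < 0.0):
            bad = [item_ids[i] for i in np.nonzero(h2 >= 1.0)[0]]
            raise ValueError(f"communality h2 must lie in [0, 1); violated by {bad}")
        object.__setattr__(self, "item_ids", item_ids)
        object.__setattr__(self, "lambda_general", lg)
        object.__setattr__(self, "lambda_specific", ls)
        object.__setattr__(self, "subscale", sub)

    # -- derived quantities -------------------------------------------------
    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def h2(self) -> np.ndarray:
        """Item communalities lam_G^2 + lam_s^2."""
        return self.lambda_general**2 + self.lambda_specific**2

    @property
    def uniqueness(self) -> np.ndarray:
        return 1.0 - self.h2

    @property
    def i_ecv(self) -> np.ndarray:
        """Item explained common variance lam_G^2 / h2 (1.0 for general-only items)."""
        h2 = self.h2
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(h2 > 0, self.lambda_general**2 / np.where(h2 > 0, h2, 1.0), np.nan)
        return out

    @property
    def subscales(self) -> tuple:
        """Distinct subscale labels, in first-appearance order."""
        seen = []
        for s in self.subscale:
            if s is not None and s not in seen:
                seen.append(s)
        return tuple(seen)

    def items_in(self, subscale: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.subscale) if s == subscale], dtype=int)

    def implied_correlations(self) -> np.ndarray:
        """Model-implied latent-response correlation matrix Lam Lam' + diag(1-h2)."""
        lam = self.to_full_matrix()
        r = lam @ lam.T
        np.fill_diagonal(r, 1.0)
        return r

    def to_full_matrix(self) -> np.ndarray:
        """(n_items, 1 + n_subscales) loading matrix, general factor first."""
        subs = self.subscales
        lam = np.zeros((self.n_items, 1 + len(subs)))
        lam[:, 0] = self.lambda_general
        for k, s in enumerate(subs):
            idx = self.items_in(s)
            lam[idx, 1 + k] = self.lambda_specific[idx]
        return lam

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": self.item_ids,
                "subscale": [s if s is not None else "" for s in self.subscale],
                "lambda_general": self.lambda_general,
                "lambda_specific": self.lambda_specific,
                "h2": self.h2,
                "i_ecv": self.i_ecv,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LoadingMatrix":
        """Build from a DataFrame with columns item_id, subscale, lambda_general, lambda_specific."""
        required = {"item_id", "subscale", "lambda_general", "lambda_specific"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"loading table missing columns: {sorted(missing)}")
        return cls(
            df["item_id"].tolist(),
            df["lambda_general"].to_numpy(float),
            df["lambda_specific"].to_numpy(float),
            df["subscale"].tolist(),
        )

    @classmethod
    def read_csv(cls, path) -> "LoadingMatrix":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class BifactorIndexSet:
    """Scale- and subscale-level bifactor indices."""

    omega_t: float
    omega_h: float
    ecv_g: float
    omega_s: dict
    omega_hs: dict
    ecv_ss: dict
    ecv_g_within: dict
    h2: pd.Series
    i_ecv: pd.Series
    n_items: int
    subscale_sizes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "omega_t": self.omega_t,
            "omega_h": self.omega_h,
            "ecv_g": self.ecv_g,
            "omega_s": dict(self.omega_s),
            "omega_hs": dict(self.omega_hs),
            "ecv_ss": dict(self.ecv_ss),
            "ecv_g_within": dict(self.ecv_g_within),
            "n_items": self.n_items,
        }


def compute_indices(loadings: LoadingMatrix) -> BifactorIndexSet:
    """Compute the full bifactor index suite from standardized loadings."""
    if loadings.n_items == 0:
        raise ValueError("empty loading matrix")
    lg = loadings.lambda_general
    ls = loadings.lambda_specific
    h2 = loadings.h2
    uniq = 1.0 - h2

    subs = loadings.subscales
    spec_sums_sq = {}
    for s in subs:
        idx = loadings.items_in(s)
        if idx.size == 0:
            raise ValueError(f"subscale {s!r} has zero items")
        spec_sums_sq[s] = float(ls[idx].sum() ** 2)

    gen_sum_sq = float(lg.sum() ** 2)
    denom = gen_sum_sq + sum(spec_sums_sq.values()) + float(uniq.sum())
    omega_t = (gen_sum_sq + sum(spec_sums_sq.values())) / denom
    omega_h = gen_sum_sq / denom

    total_common = float((lg**2).sum() + (ls**2).sum())
    ecv_g = float((lg**2).sum()) / total_common

    omega_s, omega_hs, ecv_ss, ecv_gw = {}, {}, {}, {}
    for s in subs:
        idx = loadings.items_in(s)
        g2 = float(lg[idx].sum() ** 2)
        s2 = float(ls[idx].sum() ** 2)
        u = float(uniq[idx].sum())
        d = g2 + s2 + u
        omega_s[s] = (g2 + s2) / d
        omega_hs[s] = s2 / d
        common = float((lg[idx] ** 2).sum() + (ls[idx] ** 2).sum())
        ecv_ss[s] = float((ls[idx] ** 2).sum()) / common
        ecv_gw[s] = float((lg[idx] ** 2).sum()) / common

    items = pd.Index(loadings.item_ids, name="item_id")
    return BifactorIndexSet(
        omega_t=omega_t,
        omega_h=omega_h,
        ecv_g=ecv_g,
        omega_s=omega_s,
        omega_hs=omega_hs,
        ecv_ss=ecv_ss,
        ecv_g_within=ecv_gw,
        h2=pd.Series(h2, index=items, name="h2"),
        i_ecv=pd.Series(loadings.i_ecv, index=items, name="i_ecv"),
        n_items=loadings.n_items,
        subscale_sizes={s: int(loadings.items_in(s).size) for s in subs},
    )


@dataclass(frozen=True)
class InterpretabilityDecision:
    interpretable: bool
    rule: str
    omega_h: float
    ecv_g: float


def evaluate_interpretability(
    idx: BifactorIndexSet,
    omega_h_strong: float = 0.80,
    omega_h_moderate: float = 0.70,
    ecv_g_min: float = 0.60,
) -> InterpretabilityDecision:
    """Decide whether the supra-modal (general-factor) score is interpretable.

    The score is interpretable when general-factor saturation is strong
    (omega_H >= 0.80), or moderately strong with the general factor also
    dominating common variance (omega_H >= 0.70 and ECV_G >= 0.60).
    Comparisons are inclusive.
    """
    if idx.omega_h >= omega_h_strong:
        return InterpretabilityDecision(True, "omega_h>=0.80", idx.omega_h, idx.ecv_g)
    if idx.omega_h >= omega_h_moderate and idx.ecv_g >= ecv_g_min:
        return InterpretabilityDecision(
            True, "omega_h>=0.70 & ecv_g>=0.60", idx.omega_h, idx.ecv_g
        )
    return InterpretabilityDecision(False, "below both rules", idx.omega_h, idx.ecv_g)


@dataclass(frozen=True)
class AddedValueDecision:
    subscale: str
    reliability_tier: str  # "high" (omega_s >= 0.70) or "low"
    added_value: bool
    rule: str
    omega_s: float
    omega_hs: float
    ecv_ss: float


def evaluate_added_value(idx: BifactorIndexSet) -> dict:
    """Per-subscale added-value decisions.

    High-reliability subscales (omega_S >= 0.70) add value when
    omega_HS >= 0.20 or ECV_SS >= 0.30; low-reliability subscales need
    omega_HS >= 0.25 or ECV_SS >= 0.45.
    """
    out = {}
    for s, ws in idx.omega_s.items():
        whs, ecv = idx.omega_hs[s], idx.ecv_ss[s]
        if ws >= 0.70:
            tier, whs_cut, ecv_cut = "high", 0.20, 0.30
        else:
            tier, whs_cut, ecv_cut = "low", 0.25, 0.45
        if whs >= whs_cut:
            added, rule = True, f"omega_hs>={whs_cut}"
        elif ecv >= ecv_cut:
            added, rule = True, f"ecv_ss>={ecv_cut}"
        else:
            added, rule = False, f"omega_hs<{whs_cut} & ecv_ss<{ecv_cut}"
        out[s] = AddedValueDecision(s, tier, added, rule, ws, whs, ecv)
    return out
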
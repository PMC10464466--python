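"""Synthetic multi-site data with the generative structure the analysis assumes.

Responses follow a bifactor graded-response process: each subject has an
orthogonal standard-normal general trait and one trait per specific factor;
item i's latent response is

    y_i = lam_G,i * theta_G + lam_s,i * theta_s(i) + e_i,
    e_i ~ N(0, 1 - h2_i),

and the observed ordinal category is the number of the item's strictly
increasing thresholds lying below y_i, plus one. Correlates are built so
that their within-study standardized association with a chosen generating
trait equals a per-study effect beta_j = effect + N(0, tau^2), giving the
between-study heterogeneity that the random-effects integrative models are
designed to recover. Planned missingness removes whole instrument-specific
item sets per study, emulating studies that administered only some of the
questionnaires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .indices import LoadingMatrix
from .itembank import ResponseTable, SchemaError

__all__ = [
    "BifactorSpec",
    "MultiSiteDesign",
    "CorrelateSpec",
    "default_thresholds",
    "simulate_responses",
    "simulate_multisite",
]

_LOGIT_D = 1.702


def default_thresholds(n_items: int, k: int = 5) -> np.ndarray:
    """Symmetric thresholds (same for every item) giving non-degenerate margins."""
    cuts = np.linspace(-1.2, 1.2, k - 1)
    return np.tile(cuts, (n_items, 1))


@dataclass(frozen=True)
class BifactorSpec:
    """Generating parameters: standardized loadings + per-item thresholds.

    Thresholds are on the latent-response (unit total variance) scale; with
    the probit link this makes the model-implied polychoric correlation
    matrix exactly Lam Lam' + diag(1 - h2).
    """

    loadings: LoadingMatrix
    thresholds: np.ndarray  # (n_items, K-1), strictly increasing rows
    link: str = "probit"

    def __post_init__(self):
        thr = np.asarray(self.thresholds, float)
        if thr.ndim != 2 or thr.shape[0] != self.loadings.n_items:
            raise ValueError("thresholds must be (n_items, K-1)")
        if np.any(np.diff(thr, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")
        if self.link not in ("probit", "logit"):
            raise ValueError("link must be 'probit' or 'logit'")
        object.__setattr__(self, "thresholds", thr)

    @property
    def n_items(self) -> int:
        return self.loadings.n_items

    @property
    def n_categories(self) -> int:
        return self.thresholds.shape[1] + 1

    def implied_correlations(self) -> np.ndarray:
        return self.loadings.implied_correlations()


def _draw_traits(loadings: LoadingMatrix, n: int, rng: np.random.Generator):
    subs = loadings.subscales
    theta_g = rng.standard_normal(n)
    theta_s = {s: rng.standard_normal(n) for s in subs}
    return theta_g, theta_s


def _latent_responses(spec, theta_g, theta_s, rng):
    lg = spec.loadings.lambda_general
    ls = spec.loadings.lambda_specific
    n = theta_g.shape[0]
    y = np.outer(theta_g, lg)
    for s in spec.loadings.subscales:
        idx = spec.loadings.items_in(s)
        y[:, idx] += np.outer(theta_s[s], ls[idx])
    uniq_sd = np.sqrt(spec.loadings.uniqueness)
    if spec.link == "probit":
        e = rng.standard_normal((n, spec.n_items))
    else:
        # standard logistic scaled by 1/1.702 approximates a standard normal,
        # keeping thresholds on the common latent-response scale
        e = rng.logistic(size=(n, spec.n_items)) / _LOGIT_D
    y += e * uniq_sd
    return y


def simulate_responses(
    spec: BifactorSpec,
    n: int,
    seed: int,
    study_id: str = "S1",
    return_traits: bool = False,
):
    """Simulate ``n`` subjects' ordinal responses from a bifactor spec.

    Deterministic given ``seed``. Categories are 1..K; the latent traits
    used to generate each subject are returned when ``return_traits``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    theta_g, theta_s = _draw_traits(spec.loadings, n, rng)
    y = _latent_responses(spec, theta_g, theta_s, rng)
    cats = 1 + (y[:, :, None] > spec.thresholds[None, :, :]).sum(axis=2)
    ids = [f"{study_id}-{i:06d}" for i in range(n)]
    data = pd.DataFrame(cats.astype(float), index=pd.Index(ids, name="subject_id"),
                        columns=list(spec.loadings.item_ids))
    study = pd.Series(study_id, index=data.index, name="study_id")
    table = ResponseTable(data, study, {c: spec.n_categories for c in data.columns})
    if return_traits:
        traits = pd.DataFrame({"theta_g": theta_g, **{f"theta_{s}": v for s, v in theta_s.items()}},
                              index=data.index)
        return table, traits
    return table


@dataclass(frozen=True)
class CorrelateSpec:
    """One synthetic covariate tied to a generating latent trait.

    ``effect`` is the true mean standardized effect: the within-study
    correlation r for a continuous correlate, or Cohen's d (standardized
    group difference on the trait) for a binary one. ``tau`` is the SD of
    the per-study effect.
    """

    name: str
    kind: str  # "continuous" | "binary"
    effect: float
    tau: float = 0.0
    trait: str = "theta_g"
    prevalence: float = 0.5

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError("kind must be 'continuous' or 'binary'")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass(frozen=True)
class MultiSiteDesign:
    """Multi-study design: per-study sizes, administered items, correlates."""

    n_per_study: Sequence[int]
    correlates: Sequence[CorrelateSpec] = ()
    administered: Mapping[str, Sequence[str]] | None = None  # study -> item subset
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_study) < 1:
            raise ValueError("need at least one study")
        if any(n < 1 for n in self.n_per_study):
            raise ValueError("study sizes must be >= 1")

    @property
    def study_ids(self) -> list:
        return [f"study{j+1:02d}" for j in range(len(self.n_per_study))]


def simulate_multisite(design: MultiSiteDesign, spec: BifactorSpec):
    """Simulate a pooled multi-study dataset.

    Returns ``(responses, correlates, truth)`` where ``truth`` records every
    generating value (per-study effects, traits file is not stored but
    per-study trait/correlate correlations are). Per-study random substreams
    are spawned from the master seed, so adding a study leaves earlier
    studies' data unchanged.
    """
    trait_names = ["theta_g"] + [f"theta_{s}" for s in spec.loadings.subscales]
    for c in design.correlates:
        if c.trait not in trait_names:
            raise SchemaError(f"correlate {c.name!r} targets unknown trait {c.trait!r}")

    master = np.random.SeedSequence(design.seed)
    streams = master.spawn(len(design.n_per_study))
    tables, traits_all, corr_rows = [], [], []
    truth = {"seed": design.seed, "studies": {}, "correlates": {}}
    for c in design.correlates:
        truth["correlates"][c.name] = {
            "kind": c.kind, "effect": c.effect, "tau": c.tau, "trait": c.trait,
        }

    for j, (sid, n_j, ss) in enumerate(zip(design.study_ids, design.n_per_study, streams)):
        child = ss.spawn(2 + len(design.correlates))
        seed_resp = int(child[0].generate_state(1, np.uint32)[0] % (2**31 - 1))
        table, traits = simulate_responses(spec, n_j, seed_resp, study_id=sid,
                                           return_traits=True)
        study_truth = {"n": n_j, "effects": {}}
        corr_df = pd.DataFrame(index=table.data.index)
        for ci, c in enumerate(design.correlates):
            rng = np.random.default_rng(child[2 + ci])
            beta_j = float(np.clip(c.effect + c.tau * rng.standard_normal(), -0.99, 0.99))
            th = traits[c.trait].to_numpy()
            if c.kind == "continuous":
                x = beta_j * th + np.sqrt(1 - beta_j**2) * rng.standard_normal(n_j)
            else:
                # binary group membership with standardized trait gap beta_j;
                # theta keeps unit marginal variance by construction upstream,
                # so we draw group from the trait: P(g=1|theta) chosen to give
                # within-group gap ~ beta_j at the stated prevalence.
                p = c.prevalence
                # latent-threshold assignment: g = 1{rho*theta + sqrt(1-rho^2)u > z_p}
                # with point-biserial matched to d = beta_j
                d = beta_j
                phi_z = np.exp(-0.5 * _norm_ppf(1 - p) ** 2) / np.sqrt(2 * np.pi)
                r_pb = d * np.sqrt(p * (1 - p)) / np.sqrt(1 + d**2 * p * (1 - p))
                rho = float(np.clip(r_pb * np.sqrt(p * (1 - p)) / phi_z, -0.999, 0.999))
                u = rng.standard_normal(n_j)
                lat = rho * th + np.sqrt(1 - rho**2) * u
                x = (lat > _norm_ppf(1 - p)).astype(float)
            corr_df[c.name] = x
            study_truth["effects"][c.name] = beta_j
        truth["studies"][sid] = study_truth
        traits_all.append(traits)
        tables.append(table)
        corr_rows.append(corr_df)

    data = pd.concat([t.data for t in tables])
    study = pd.concat([t.study_id for t in tables])
    if design.administered is not None:
        for sid, items in design.administered.items():
            drop = [c for c in data.columns if c not in set(items)]
            data.loc[study == sid, drop] = np.nan
        keep = ~data.isna().all(axis=1)
        data, study = data.loc[keep], study.loc[keep]
    responses = ResponseTable(data, study,
                              {c: spec.n_categories for c in data.columns})
    correlates = pd.concat(corr_rows)
    correlates.insert(0, "study_id", study.loc[correlates.index])
    correlates = correlates.reset_index(names="subject_id")
    truth["traits"] = pd.concat(traits_all)
    return responses, correlates, truth


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))
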
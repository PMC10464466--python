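"""End-to-end orchestration: refine -> bifactor -> decide -> score -> IDA.

Stages mirror the analytic workflow for each sensory response pattern
(HYPER / HYPO / SEEK):

1. ``run_refinement`` — per modality x pattern subconstruct: ICLUST-based
   iterative item removal, unidimensional GRM fit, adequacy gates. A
   subconstruct starting with fewer than 3 items is flagged not scalable;
   one failing gates (or left with < 3 items) is flagged for a single-item
   fallback, whose choice is a configuration decision, never automated.
2. ``run_bifactor`` — EGA structure check, confirmatory bifactor GRM
   (single-item subconstructs load on the general factor only), fit gates
   with an automatic revision path that refits without the single-item
   indicators when gates fail, bifactor indices, and the interpretability /
   added-value decisions.
3. ``run_correlates`` — plausible-value scoring of every interpretable
   construct and one Bayesian random-effects IDA model per construct x
   correlate meeting the minimum-cases rule, collected into an effect
   matrix with evidence classes.

Every artifact dictionary embeds the package version, seed, and a hash of
the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping

import pandas as pd

from . import __version__
from .fitstats import apply_gates, limited_info_chisq
from .grm import eap_scores, fit_grm, plausible_values, standardize_loadings
from .ida import IDAModelSpec, fit_ida
from .indices import compute_indices, evaluate_added_value, evaluate_interpretability
from .itembank import ItemBank, ItemDefinition, ResponseTable
from .structure import ega, iclust_refine, polychoric

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_refinement", "run_bifactor", "run_correlates",
           "synthetic_bank"]


@dataclass
class PipelineConfig:
    """Options shared across pipeline stages."""

    seed: int = 0
    n_quad: int = 21
    em_tol: float = 1e-4
    max_iter: int = 200
    loading_cut: float = 0.30
    min_pair_n: int = 30
    m_pv: int = 10
    min_cases: int = 100
    min_items: int = 3
    single_item_fallback: Mapping[str, str] = field(default_factory=dict)
    ida: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"version": __version__, "seed": self.seed,
                "config_hash": self.config_hash()}


def synthetic_bank(loadings, pattern: str) -> ItemBank:
    """An ItemBank whose harmonized groups are the columns of a loading matrix.

    Convenience for synthetic runs: each harmonized item becomes its own
    homolog group; modality is the item's subscale (or 'General'). Marked
    synthetic — it mirrors the structure, not the content, of the real
    instrument item map.
    """
    items = []
    for i, iid in enumerate(loadings.item_ids):
        # general-only items act as their own single-indicator subconstructs
        sub = loadings.subscale[i] or f"single:{iid}"
        items.append(ItemDefinition(iid, "OTHER", sub, pattern, False, iid, 5))
    return ItemBank(items)


# ---------------------------------------------------------------------------
# stage 1: refinement


def run_refinement(bank: ItemBank, table: ResponseTable,
                   config: PipelineConfig | None = None) -> dict:
    """Refine each modality x pattern subconstruct and gate its 1-D GRM.

    Returns {(pattern, modality): report-dict}; report fields include the
    retained item set, fit indices, gate verdicts, and status flags
    ("ok", "fallback" when gates fail or too few items survive, or
    "not_scalable" for < 3 initial items).
    """
    config = config or PipelineConfig()
    groups = bank.homolog_groups()
    group_meta = {g: bank[members[0]] for g, members in groups.items()}
    reports = {}
    for pattern in sorted({m.pattern for m in group_meta.values()}):
        for modality in sorted({m.modality for m in group_meta.values()
                                if m.pattern == pattern}):
            key = (pattern, modality)
            items = [g for g, m in group_meta.items()
                     if m.pattern == pattern and m.modality == modality
                     and g in set(table.items)]
            rep = {"initial_items": items, "provenance": config.provenance()}
            if len(items) < config.min_items:
                rep.update(status="not_scalable",
                           reason=f"fewer than the requisite {config.min_items} "
                                  "items for a unidimensional GRM")
                reports[key] = rep
                continue
            sub = table.subset_items(items)
            sim = polychoric(sub, min_pair_n=config.min_pair_n)
            retained, tree, removals = iclust_refine(sim, config.loading_cut)
            rep["retained_items"] = retained
            rep["removals"] = removals
            if len(retained) < config.min_items:
                rep.update(status="fallback",
                           reason="fewer than 3 items survived refinement",
                           fallback_item=config.single_item_fallback.get(
                               f"{pattern}/{modality}"))
                reports[key] = rep
                continue
            scale = table.subset_items(retained)
            model = fit_grm(scale, n_quad=config.n_quad, tol=config.em_tol,
                            max_iter=config.max_iter)
            fit = limited_info_chisq(model, scale)
            lam = standardize_loadings(model, force=True)
            idx = compute_indices(lam)
            scores = eap_scores(model, scale, force=True)
            verdict = apply_gates(fit, scores.marginal_reliability["theta_g"],
                                  idx.omega_t, n_items=len(retained))
            rep.update(
                status="ok" if verdict.overall else "fallback",
                model=model, fit=fit, gates=verdict,
                rho_xx=scores.marginal_reliability["theta_g"],
                omega_t=idx.omega_t,
                table2_row={
                    "n_initial": len(items), "n_final": len(retained),
                    "tli": fit.tli, "rmsea": fit.rmsea, "srmr": fit.srmr,
                    "rho_xx": scores.marginal_reliability["theta_g"],
                    "omega_t": idx.omega_t,
                    "retained": verdict.overall,
                },
            )
            if not verdict.overall:
                rep["fallback_item"] = config.single_item_fallback.get(
                    f"{pattern}/{modality}")
            reports[key] = rep
    return reports


# ---------------------------------------------------------------------------
# stage 2: bifactor model + decisions


def run_bifactor(table: ResponseTable, refinement: dict, pattern: str,
                 config: PipelineConfig | None = None) -> dict:
    """Bifactor GRM for one response pattern, with the revision path.

    Multi-item refined subconstructs become specific factors; single-item
    fallbacks load on the general factor only. If the initial model fails
    the fit gates, it is refit without the single-item indicators and both
    fits are recorded.
    """
    config = config or PipelineConfig()
    structure: dict = {}
    single_items: list = []
    for (pat, modality), rep in refinement.items():
        if pat != pattern:
            continue
        if rep["status"] == "ok":
            for it in rep["retained_items"]:
                structure[it] = modality
        elif rep["status"] == "not_scalable" and len(rep["initial_items"]) == 2:
            # too few items for a unidimensional scale, but still a valid
            # 2-item specific factor in the bifactor model
            for it in rep["initial_items"]:
                structure[it] = modality
        else:
            fb = rep.get("fallback_item")
            if fb is None and len(rep["initial_items"]) == 1:
                # a one-item subconstruct leaves no choice to configure
                fb = rep["initial_items"][0]
            if fb is not None:
                structure[fb] = None
                single_items.append(fb)
            else:
                log.info("subconstruct %s/%s: no fallback item configured; "
                         "omitted from bifactor model", pat, modality)
    multi_subs = {s for s in structure.values() if s is not None}
    if len(multi_subs) < 2:
        raise ValueError(
            f"pattern {pattern}: bifactor model needs >= 2 multi-item "
            "subconstructs; use the unidimensional path"
        )
    items = [i for i in structure if i in set(table.items)]
    sub = table.subset_items(items)

    community = ega(sub, min_pair_n=config.min_pair_n)
    out = {"pattern": pattern, "structure": dict(structure),
           "ega": community, "provenance": config.provenance()}

    def _fit(item_set):
        d = table.subset_items(item_set)
        m = fit_grm(d, {i: structure[i] for i in item_set},
                    n_quad=config.n_quad, tol=config.em_tol,
                    max_iter=config.max_iter)
        f = limited_info_chisq(m, d)
        lam = standardize_loadings(m, force=True)
        idx = compute_indices(lam)
        sc = eap_scores(m, d, force=True)
        v = apply_gates(f, sc.marginal_reliability["theta_g"], idx.omega_t,
                        n_items=len(item_set))
        return {"model": m, "fit": f, "loadings": lam, "indices": idx,
                "gates": v, "scores": sc, "items": list(item_set)}

    first = _fit(items)
    out["initial_fit"] = first
    final = first
    if not first["gates"].overall and single_items:
        revised_items = [i for i in items if i not in set(single_items)]
        log.info("pattern %s: gates failed; refitting without single-item "
                 "indicators %s", pattern, single_items)
        revised = _fit(revised_items)
        out["revised_fit"] = revised
        final = revised
    if not final["model"].converged:
        raise RuntimeError(f"pattern {pattern}: bifactor GRM did not converge")
    out["final_fit"] = final
    out["interpretability"] = evaluate_interpretability(final["indices"])
    out["added_value"] = evaluate_added_value(final["indices"])
    return out


# ---------------------------------------------------------------------------
# stage 3: correlates


def _infer_kind(x: pd.Series) -> str:
    vals = x.dropna().unique()
    return "binary" if len(vals) <= 2 else "continuous"


def run_correlates(table: ResponseTable, correlates: pd.DataFrame,
                   bifactor_results: Mapping[str, dict],
                   config: PipelineConfig | None = None):
    """IDA models for every interpretable construct x correlate pair.

    Interpretable constructs: the general factor of a pattern whose
    supra-modal score passed the interpretability rules (scored from the
    bifactor model), and each subscale with added value (scored from a
    unidimensional GRM on its items). Returns (effect_matrix, results)
    where cells hold "median (class)" strings.
    """
    config = config or PipelineConfig()
    constructs = {}  # name -> (model, data, trait)
    for pattern, res in bifactor_results.items():
        final = res["final_fit"]
        if res["interpretability"].interpretable:
            constructs[f"{pattern} (general)"] = (
                final["model"], table.subset_items(final["items"]), "theta_g")
        for s, dec in res["added_value"].items():
            if not dec.added_value:
                continue
            sub_items = [i for i in final["items"] if res["structure"].get(i) == s]
            if len(sub_items) < config.min_items:
                continue
            d = table.subset_items(sub_items)
            m = fit_grm(d, n_quad=config.n_quad, tol=config.em_tol,
                        max_iter=config.max_iter)
            constructs[f"{pattern} {s}"] = (m, d, "theta_g")
    if not constructs:
        return pd.DataFrame(), {"note": "zero interpretable constructs",
                                "provenance": config.provenance()}

    corr = correlates.set_index("subject_id")
    study_all = corr["study_id"]
    cov_cols = [c for c in corr.columns if c != "study_id"]
    results: dict = {}
    matrix = pd.DataFrame(index=list(constructs), columns=cov_cols, dtype=object)
    for cname, (model, data, trait) in constructs.items():
        for cov in cov_cols:
            # plausible values conditioned on the analyzed covariate, so the
            # secondary regression of PV on covariate is unbiased
            cond = corr[[cov]].reindex(data.data.index)
            pvs = plausible_values(model, data, m=config.m_pv, seed=config.seed,
                                   trait=trait, conditioning=cond, force=True)
            pv = pvs.draws
            x = corr[cov].reindex(pv.index)
            kind = _infer_kind(x)
            spec = IDAModelSpec(predictor_kind=kind, min_cases=config.min_cases,
                                seed=config.seed, **config.ida)
            res = fit_ida(spec, pv, x, study_all.reindex(pv.index))
            results[(cname, cov)] = res
            if res.skipped_reason:
                matrix.loc[cname, cov] = f"not fit ({res.skipped_reason})"
            else:
                matrix.loc[cname, cov] = f"{res.median:+.3f} ({res.evidence})"
    results["provenance"] = config.provenance()
    return matrix, results
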
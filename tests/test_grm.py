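"""GRM engine: likelihood oracles, EM fitting, standardization, scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sensescale.grm import (
    GRMModel,
    eap_scores,
    fit_grm,
    gauss_hermite,
    grm_loglik,
    model_from_spec,
    plausible_values,
    slopes_from_loadings,
    standardize_loadings,
    _cat_probs,
)
from sensescale.indices import LoadingMatrix
from sensescale.itembank import ResponseTable
from sensescale.synth import BifactorSpec, default_thresholds, simulate_responses


def _table(arr, items=None, k=5):
    arr = np.asarray(arr, float)
    items = items or [f"i{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, columns=items,
                      index=pd.Index([f"s{i}" for i in range(arr.shape[0])],
                                     name="subject_id"))
    study = pd.Series("A", index=df.index, name="study_id")
    return ResponseTable(df, study, {i: k for i in items})


# ---------------------------------------------------------------------------
# likelihood oracles


def test_slope_free_item_loglik_is_marginal_frequency():
    """a=0 factorizes: loglik = sum log of threshold-implied category mass."""
    thr = np.array([-1.0, 0.0, 0.5, 1.5])
    m = GRMModel(["i0"], [0.0], [0.0], [thr], [None], converged=True)
    data = _table([[1], [3], [5], [3]])
    probs = np.diff(np.concatenate([[0], norm.cdf(thr), [1]]))
    expected = np.log(probs[0]) + 2 * np.log(probs[2]) + np.log(probs[4])
    assert grm_loglik(m, data) == pytest.approx(expected, abs=1e-9)


def test_unidimensional_loglik_matches_dense_trapezoid_oracle():
    """3-item model, 5 subjects: quadrature vs brute-force grid integration."""
    rng = np.random.default_rng(5)
    thr = [np.sort(rng.normal(0, 1, 4)) for _ in range(3)]
    a = np.array([0.8, 1.4, 1.1])
    m = GRMModel([f"i{j}" for j in range(3)], a, np.zeros(3), thr,
                 [None] * 3, n_quad=101, converged=True)
    data = _table(rng.integers(1, 6, size=(5, 3)))

    # independent oracle: dense trapezoid over theta
    grid = np.linspace(-8, 8, 4001)
    dens = norm.pdf(grid)
    ll = 0.0
    codes = data.data.to_numpy(int) - 1
    for i in range(5):
        like = np.ones_like(grid)
        for j in range(3):
            like *= _cat_probs(a[j] * grid, thr[j])[:, codes[i, j]]
        ll += np.log(np.trapezoid(like * dens, grid))
    assert grm_loglik(m, data) == pytest.approx(ll, abs=1e-6)


def test_bifactor_dimension_reduction_matches_naive_quadrature():
    """6-item, 2-specific toy: reduced 2-D blocks equal the full 3-D cube."""
    lam = LoadingMatrix([f"i{j}" for j in range(6)],
                        [0.5, 0.4, 0.6, 0.5, 0.45, 0.55],
                        [0.5, 0.6, 0.4, 0.55, 0.5, 0.45],
                        ["A", "A", "A", "B", "B", "B"])
    spec = BifactorSpec(lam, default_thresholds(6))
    data = simulate_responses(spec, 12, seed=1)
    m = model_from_spec(spec)
    ll = grm_loglik(m, data)

    x, w = gauss_hermite(21)
    codes = data.data.to_numpy(int) - 1
    ag, asp, thr = m.a_general, m.a_specific, m.thresholds
    tot = 0.0
    for i in range(codes.shape[0]):
        cube = np.ones((21, 21, 21))
        for j in range(6):
            th = x[:, None] if j < 3 else x[None, :]
            lin = ag[j] * x[:, None, None] + (
                asp[j] * (x[None, :, None] if j < 3 else x[None, None, :]))
            pj = _cat_probs(lin, thr[j])[:, :, :, codes[i, j]]
            cube *= pj
        tot += np.log(np.einsum("q,a,b,qab->", w, w, w, cube))
    assert ll == pytest.approx(tot, abs=1e-4)


# ---------------------------------------------------------------------------
# standardization


def test_standardization_closed_forms():
    m = GRMModel(["i0", "i1"], [1.0, 0.0], [0.0, 0.0],
                 [np.array([0.0])] * 2, [None, None], converged=True)
    lam = standardize_loadings(m)
    assert lam.lambda_general[0] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
    assert lam.lambda_general[1] == 0.0
    assert lam.h2[1] == 0.0


def test_standardization_round_trip(hypo_loadings):
    ag, asp = slopes_from_loadings(hypo_loadings)
    denom = np.sqrt(1 + ag**2 + asp**2)
    assert np.allclose(ag / denom, hypo_loadings.lambda_general, atol=1e-10)
    assert np.allclose(asp / denom, hypo_loadings.lambda_specific, atol=1e-10)


# ---------------------------------------------------------------------------
# fitting


def test_unidimensional_parameter_recovery():
    lam = LoadingMatrix([f"i{j}" for j in range(4)],
                        [0.62, 0.71, 0.55, 0.66], [0.0] * 4, [None] * 4)
    spec = BifactorSpec(lam, default_thresholds(4))
    data = simulate_responses(spec, 2000, seed=7)
    m = fit_grm(data, tol=1e-5, max_iter=300)
    assert m.converged
    true_a, _ = slopes_from_loadings(lam)
    true_thr = [spec.thresholds[j] / np.sqrt(lam.uniqueness[j]) for j in range(4)]
    assert np.all(np.abs(m.a_general - true_a) < 0.15)
    for j in range(4):
        assert np.all(np.abs(m.thresholds[j] - true_thr[j]) < 0.15)


def test_em_loglik_monotone_and_history_recorded(hypo_fit_3000):
    h = np.asarray(hypo_fit_3000.loglik_history)
    assert np.all(np.diff(h) >= -1e-6 * np.abs(h[:-1]))
    assert hypo_fit_3000.converged


def test_fitted_loglik_beats_generating_parameters(hypo_fit_3000, hypo_spec,
                                                   hypo_sample_3000):
    gen = model_from_spec(hypo_spec)
    assert grm_loglik(hypo_fit_3000, hypo_sample_3000) >= \
        grm_loglik(gen, hypo_sample_3000) - 1.0


def test_too_few_items_rejected_with_rule():
    data = _table(np.tile([1, 2, 3, 4, 5], (2, 1)).T[:, :2])
    with pytest.raises(ValueError, match="requisite 3"):
        fit_grm(data)


def test_degenerate_constant_item_rejected():
    arr = np.column_stack([np.full(50, 3.0),
                           np.tile([1, 2, 3, 4, 5], 10),
                           np.tile([5, 4, 3, 2, 1], 10)])
    with pytest.raises(ValueError, match="fewer than 2 observed categories"):
        fit_grm(_table(arr))


def test_empty_category_collapsed_with_remap():
    rng = np.random.default_rng(3)
    arr = rng.choice([1.0, 2.0, 4.0, 5.0], size=(300, 3))  # category 3 never used
    m = fit_grm(_table(arr), tol=1e-3, max_iter=100)
    assert all(t.size == 3 for t in m.thresholds)  # 4 observed categories
    assert set(m.category_remaps) == {"i0", "i1", "i2"}


def test_model_json_round_trip(hypo_fit_3000, tmp_path):
    p = tmp_path / "model.json"
    hypo_fit_3000.to_json(p)
    back = GRMModel.from_json(str(p))
    assert back.item_ids == hypo_fit_3000.item_ids
    assert np.allclose(back.a_general, hypo_fit_3000.a_general)
    assert back.subscale == hypo_fit_3000.subscale


# ---------------------------------------------------------------------------
# scoring


@pytest.fixture(scope="module")
def toy_model_and_data():
    lam = LoadingMatrix([f"i{j}" for j in range(4)],
                        [0.6, 0.7, 0.5, 0.65], [0.0] * 4, [None] * 4)
    spec = BifactorSpec(lam, default_thresholds(4))
    return model_from_spec(spec), simulate_responses(spec, 2000, seed=13), lam


def test_all_missing_subject_scored_at_prior_and_flagged(toy_model_and_data):
    """A subject with no modeled responses gets the prior (0, 1) and a flag."""
    model, data, _ = toy_model_and_data
    df = data.data.iloc[:10].copy()
    df.iloc[0, :] = np.nan
    # all-missing rows violate the table invariant by design; build directly
    table = ResponseTable.__new__(ResponseTable)
    table.data = df
    table.study_id = data.study_id.iloc[:10]
    table.n_categories = data.n_categories
    s = eap_scores(model, table)
    assert s.all_missing.iloc[0]
    assert s.eap["theta_g"].iloc[0] == 0.0
    assert s.psd["theta_g"].iloc[0] == 1.0


def test_information_monotonicity_stronger_slopes_smaller_psd(toy_model_and_data):
    model, data, _ = toy_model_and_data
    strong = GRMModel(model.item_ids, model.a_general * 2, model.a_specific * 2,
                      model.thresholds, model.subscale, converged=True)
    weak_psd = eap_scores(model, data).psd["theta_g"].mean()
    strong_psd = eap_scores(strong, data).psd["theta_g"].mean()
    assert strong_psd < weak_psd


def test_marginal_reliability_matches_generating_model(toy_model_and_data):
    """rho_xx from EAP scoring approximates the generating model's reliability."""
    model, data, lam = toy_model_and_data
    s = eap_scores(model, data)
    # independent oracle: Monte-Carlo reliability = var(EAP)/var(theta-hat+E)
    # using the known simulation truth: correlation(EAP, true theta)^2 ~ rho
    spec = BifactorSpec(lam, default_thresholds(4))
    _, traits = simulate_responses(spec, 2000, seed=13, return_traits=True)
    r2 = np.corrcoef(s.eap["theta_g"], traits["theta_g"])[0, 1] ** 2
    assert s.marginal_reliability["theta_g"] == pytest.approx(r2, abs=0.03)


def test_plausible_values_mean_and_dispersion(toy_model_and_data):
    model, data, _ = toy_model_and_data
    s = eap_scores(model, data)
    pv = plausible_values(model, data, m=200, seed=5)
    assert np.allclose(pv.draws.mean(axis=1), s.eap["theta_g"], atol=0.15)
    assert pv.draws.to_numpy().var() >= s.eap["theta_g"].var()


def test_plausible_values_deterministic_and_validated(toy_model_and_data):
    model, data, _ = toy_model_and_data
    a = plausible_values(model, data, m=3, seed=9)
    b = plausible_values(model, data, m=3, seed=9)
    pd.testing.assert_frame_equal(a.draws, b.draws)
    with pytest.raises(ValueError, match="M"):
        plausible_values(model, data, m=0, seed=1)


def test_specific_trait_scores_available(hypo_fit_3000, hypo_sample_3000):
    s = eap_scores(hypo_fit_3000, hypo_sample_3000)
    assert "theta_Speech" in s.eap.columns
    assert (s.psd[["theta_g", "theta_Speech"]] > 0).all().all()
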
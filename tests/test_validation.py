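"""Cross-validation mechanics and agreement metrics."""

import numpy as np
import pandas as pd
import pytest

from stlur.regression import fit_no_intercept, manual_r2
from stlur.terms import parse_term
from stlur.validation import (
    BackyardCorrection,
    bland_altman,
    estimate_backyard_correction,
    evaluate,
    external_validate,
    kfold_cv,
    weighted_kappa_quartiles,
)


def toy(n=30, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"a": rng.uniform(1, 5, n), "b": rng.uniform(0, 2, n)})
    y = 0.6 * df.a + 0.9 * df.b + rng.normal(0, 0.3, n)
    return df, y.to_numpy()


def test_kfold_equals_explicit_loo_at_k_n():
    df, y = toy(30)
    terms = [parse_term("a"), parse_term("b")]
    got = kfold_cv(terms, df, y, k=30, seed=0)
    X = np.column_stack([df.a, df.b])
    loo = np.empty(30)
    for i in range(30):
        keep = np.arange(30) != i
        fit = fit_no_intercept(y[keep], X[keep])
        loo[i] = X[i] @ fit.beta
    np.testing.assert_allclose(np.sort(got), np.sort(loo), rtol=1e-10)
    np.testing.assert_allclose(got, loo, rtol=1e-10)  # same observation order


def test_kfold_noiseless_gives_cv_r2_one_and_partition():
    df, _ = toy(50, seed=1)
    y = 0.6 * df.a.to_numpy() + 0.9 * df.b.to_numpy()
    terms = [parse_term("a"), parse_term("b")]
    preds = kfold_cv(terms, df, y, k=10, seed=2)
    assert manual_r2(y, preds) == pytest.approx(1.0, abs=1e-8)
    # every observation predicted exactly once: preds has no sentinel left
    assert np.isfinite(preds).all()


def test_kfold_seed_reproducible_and_k_guard():
    df, y = toy(40, seed=3)
    terms = [parse_term("a"), parse_term("b")]
    p1 = kfold_cv(terms, df, y, k=10, seed=7)
    p2 = kfold_cv(terms, df, y, k=10, seed=7)
    np.testing.assert_array_equal(p1, p2)
    with pytest.raises(ValueError, match="smaller k"):
        kfold_cv(terms, df.iloc[:4], y[:4], k=2, seed=0)


def test_evaluate_perfect_prediction_identities():
    rng = np.random.default_rng(4)
    obs = np.exp(rng.normal(3, 0.4, 50))
    rep_log = evaluate(obs, np.log(obs), "log")
    rep_c = evaluate(obs, np.log(obs), "concentration")
    assert rep_log.pearson_r == pytest.approx(1.0)
    assert rep_log.r2 == pytest.approx(1.0)
    assert rep_c.rmse == pytest.approx(0.0, abs=1e-10)
    assert rep_c.bland_altman_mean == pytest.approx(0.0, abs=1e-10)


def test_evaluate_constant_predictions_flagged_degenerate():
    rng = np.random.default_rng(5)
    obs = np.exp(rng.normal(3, 0.4, 50))
    rep = evaluate(obs, np.full(50, 3.0), "log")
    assert rep.degenerate
    assert rep.r2 <= 0


def test_evaluate_matches_direct_formula_oracle():
    rng = np.random.default_rng(6)
    obs = np.exp(rng.normal(3, 0.4, 200))
    pred_log = np.log(obs) + rng.normal(0, 0.2, 200)
    rep = evaluate(obs, pred_log, "concentration")
    pred = np.exp(pred_log)
    assert rep.rmse == pytest.approx(float(np.sqrt(np.mean((obs - pred) ** 2))))
    r_oracle = float(np.corrcoef(obs, pred)[0, 1])
    assert rep.pearson_r == pytest.approx(r_oracle, rel=1e-10)
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    assert rep.r2 == pytest.approx(1 - sse / sst, rel=1e-10)
    with pytest.raises(ValueError):
        evaluate(np.array([1.0, -1.0, 2.0]), np.zeros(3), "log")


def test_bland_altman_offset_and_proportional_bias():
    rng = np.random.default_rng(7)
    obs = rng.normal(20, 5, 100)
    m, s = bland_altman(obs, obs)
    assert (m, s) == (pytest.approx(0.0), pytest.approx(0.0, abs=1e-10))
    m, s = bland_altman(obs, obs + 2.0)
    assert m == pytest.approx(2.0)
    assert s == pytest.approx(0.0, abs=1e-10)
    pred = 1.3 * obs
    m, s = bland_altman(obs, pred)
    diff, mean = pred - obs, (pred + obs) / 2
    slope_oracle = float(np.cov(mean, diff)[0, 1] / np.var(mean, ddof=1))
    assert s == pytest.approx(slope_oracle, rel=1e-8)


def test_weighted_kappa_identity_symmetry_and_null():
    rng = np.random.default_rng(8)
    x = rng.normal(size=400)
    assert weighted_kappa_quartiles(x, x) == 1.0
    y = x + rng.normal(0, 0.5, 400)
    assert weighted_kappa_quartiles(x, y) == pytest.approx(
        weighted_kappa_quartiles(y, x + 0), abs=0.2
    )
    # independent vectors: kappa near 0 over Monte-Carlo draws
    kappas = [
        weighted_kappa_quartiles(rng.normal(size=500), rng.normal(size=500))
        for _ in range(20)
    ]
    assert abs(float(np.mean(kappas))) < 0.05


def test_weighted_kappa_hand_computed_confusion_table():
    # classes chosen so the shared quartile binning is the identity mapping
    obs = np.repeat([0.0, 1.0, 2.0, 3.0], 4)
    pred = obs.copy()
    pred[0] = 3.0  # one gross misclassification 0 -> 3
    pred[5] = 2.0  # one near miss 1 -> 2
    got = weighted_kappa_quartiles(obs, pred)
    cuts = np.quantile(obs, [0.25, 0.5, 0.75])
    co, cp = np.digitize(obs, cuts), np.digitize(pred, cuts)
    O = np.zeros((4, 4))
    for a, b in zip(co, cp):
        O[a, b] += 1
    O /= O.sum()
    marg_o, marg_p = O.sum(1), O.sum(0)
    W = 1 - np.abs(np.subtract.outer(range(4), range(4))) / 3
    E = np.outer(marg_o, marg_p)
    kappa = ((W * O).sum() - (W * E).sum()) / (1 - (W * E).sum())
    assert got == pytest.approx(kappa, rel=1e-10)


def test_weighted_kappa_tie_guard():
    with pytest.raises(ValueError, match="bin"):
        weighted_kappa_quartiles(np.ones(20), np.ones(20))


def test_backyard_correction_recovery_and_closure():
    rng = np.random.default_rng(9)
    n = 600
    backyard = rng.random(n) < 0.4
    resid = rng.normal(0, 0.2, n)
    resid[backyard] -= np.log(1.275)
    corr = estimate_backyard_correction(resid, backyard, "rural")
    assert corr.factor("rural") == pytest.approx(1.275, rel=0.05)
    corrected = resid.copy()
    corrected[backyard] += np.log(corr.factor("rural"))
    assert corrected[backyard].mean() == pytest.approx(
        corrected[~backyard].mean(), abs=1e-12
    )
    with pytest.raises(ValueError, match="backyard"):
        estimate_backyard_correction(resid, np.zeros(n, bool), "rural")


def test_external_validate_routes_by_region_tag():
    rng = np.random.default_rng(10)
    n = 60
    df = pd.DataFrame({"a": rng.uniform(1, 5, n)})
    y = 0.7 * df.a.to_numpy() + rng.normal(0, 0.1, n)
    from stlur.regression import fit_terms

    fit_r = fit_terms([parse_term("a")], df, y)
    fit_u = fit_terms([parse_term("a")], df, y + 1.0)  # deliberately different
    meas = pd.DataFrame(
        {
            "no2": np.exp(y),
            "region_kind": ["rural"] * n,
            "backyard": [False] * n,
        }
    )
    reps = external_validate({"rural": fit_r, "urban": fit_u}, meas, df)
    assert reps["log"].r2 > 0.8  # rural model used, not the shifted urban one
    assert reps["concentration"].kappa_quartiles is not None
    meas_bad = meas.assign(region_kind="alpine")
    with pytest.raises(ValueError, match="alpine"):
        external_validate({"rural": fit_r}, meas_bad, df)


def test_backyard_correction_applied_before_comparison():
    rng = np.random.default_rng(11)
    n = 80
    df = pd.DataFrame({"a": rng.uniform(1, 5, n)})
    y = 0.7 * df.a.to_numpy()
    from stlur.regression import fit_terms

    fit = fit_terms([parse_term("a")], df, y)
    backyard = rng.random(n) < 0.5
    obs = np.exp(y)
    obs[backyard] /= 1.275
    meas = pd.DataFrame(
        {"no2": obs, "region_kind": "rural", "backyard": backyard}
    )
    corr = BackyardCorrection(factor_rural=1.275)
    reps = external_validate({"rural": fit}, meas, df, corr)
    assert reps["log"].r2 == pytest.approx(1.0, abs=1e-9)
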
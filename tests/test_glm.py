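"""Poisson GLM: fitting, convexity, cross-validation, model comparison."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import ofc_encoding as oe
from ofc_encoding.glm import poisson_nll, predict_rate, r2_heldout, smooth_boxcar


@pytest.fixture(scope="module")
def zero_design(design):
    return dataclasses.replace(design, X=np.zeros_like(design.X),
                               streams=np.zeros_like(design.streams))


def test_constant_unit_zero_design_recovers_log_mean(null_spikes, zero_design):
    fit = oe.fit_glm(null_spikes.binned_counts, zero_design, xi=1.0)
    assert abs(fit.theta0 - np.log(0.25)) < 0.05
    assert np.all(np.abs(fit.theta[:-1]) < 1e-8)


def test_ridge_limit_shrinks_kernels(archetype_spikes, design):
    sp = archetype_spikes[2]
    fit = oe.fit_glm(sp.binned_counts, design, xi=1e7)
    assert np.max(np.abs(fit.theta[:-1])) < 1e-2
    mean = sp.binned_counts.mean()
    assert abs(fit.theta0 - np.log(mean)) < 0.15


def test_objective_is_convex_unique_minimum(archetype_spikes, design):
    # refits from random initializations agree in theta
    sp = archetype_spikes[4]
    rng = np.random.default_rng(0)
    thetas = []
    for _ in range(4):
        init = rng.normal(scale=0.3, size=design.X.shape[1] + 1)
        fit = oe.fit_glm(sp.binned_counts, design, xi=1.0, theta_init=init)
        thetas.append(fit.theta)
    for th in thetas[1:]:
        assert np.max(np.abs(th - thetas[0])) < 1e-4


def test_negative_penalty_rejected(null_spikes, design):
    with pytest.raises(ValueError):
        oe.fit_glm(null_spikes.binned_counts, design, xi=-1.0)


def test_kernel_covariance_psd(archetype_fits):
    cov = archetype_fits[2].kernel_cov
    assert cov is not None
    assert np.allclose(cov, cov.T)
    vals = np.linalg.eigvalsh(cov)
    assert vals.min() > -1e-10 * vals.max()


def test_kernel_recovery_at_400_trials(basis):
    cfg = oe.TaskConfig(n_trials=400, seed=17)
    s = oe.generate_session(cfg, seed=17)
    d = oe.build_design_matrix(s, basis=basis)
    nrn = oe.make_archetypes(cfg, seed=3, basis=basis)[2]
    sp = oe.simulate_spikes(s, nrn, seed=18, basis=basis)
    fit = oe.fit_glm(sp.binned_counts, d, xi=0.5)
    corrs = oe.kernel_recovery(nrn, fit, basis)
    assert corrs  # at least one substantial kernel
    assert np.median(list(corrs.values())) >= 0.8


def test_partition_balance_and_determinism(session, scheme):
    labels2 = oe.partition_trials(session, seed=0).labels
    assert np.array_equal(scheme.labels, labels2)
    counts = np.bincount(scheme.labels)[1:]
    assert counts.max() - counts.min() <= 1
    rep = scheme.balance_report
    for col in ("win", "loss", "left", "right"):
        assert rep[col].max() - rep[col].min() <= 1
    table = rep[["win", "loss"]].to_numpy()
    chi2 = scipy.stats.chi2_contingency(table)
    assert chi2.pvalue > 0.9


def test_partition_balance_even_split():
    # 50/50 outcomes -> each partition carries 10 +/- 1 wins
    cfg = oe.TaskConfig(n_trials=100, probability_levels=(0.0, 1.0),
                        p_opt_out=0.0, seed=5)
    s = oe.generate_session(cfg, seed=5)
    sch = oe.partition_trials(s, seed=1)
    wins = sch.balance_report["win"]
    assert all(abs(w - wins.mean()) <= 1 for w in wins)


def test_select_model_argmin_contract_and_noise_r2(null_spikes, design, scheme):
    fit = oe.select_model(null_spikes.binned_counts, design, scheme,
                          n_grid=3, n_rounds=1, compute_cov=False)
    # selected model attains the lowest test NLL among evaluated grid points
    nlls = [nll for _, nll in fit.search_history]
    assert fit.nll_test == pytest.approx(min(nlls))
    # a pure-noise unit explains essentially nothing held out
    assert fit.r2_test < 0.05


def test_r2_of_mean_model_is_zero(null_spikes, design, scheme):
    test_trials = scheme.trials_in([scheme.test_partition])
    y = null_spikes.binned_counts
    theta = np.zeros(design.X.shape[1] + 1)
    theta[-1] = np.log(y[test_trials].mean())
    fit = oe.GLMFit(theta=theta, variables=design.variables,
                    n_basis=design.basis.n_basis, xi=0.0, nll_train=0.0,
                    converged=True)
    assert r2_heldout(fit, y, design, test_trials) == pytest.approx(0.0,
                                                                    abs=0.02)


def test_r2_of_perfect_prediction_is_one(archetype_fits, design, scheme):
    fit = archetype_fits[0]
    test_trials = scheme.trials_in([scheme.test_partition])
    exact = predict_rate(fit.theta, design.X).reshape(design.n_trials, -1)
    assert r2_heldout(fit, exact, design, test_trials) == pytest.approx(1.0)


def test_r2_with_ground_truth_rates_improves_with_trials(
        basis, archetype_neurons):
    # ground-truth rates as the "model" explain the empirical PSTH, and
    # more so with more trials as trial-averaging removes Poisson noise
    nrn = archetype_neurons[2]
    r2_single, r2_psth = [], []
    for n_trials, seed in ((40, 31), (200, 32)):
        cfg = oe.TaskConfig(n_trials=n_trials, seed=seed)
        s = oe.generate_session(cfg, seed=seed)
        d = oe.build_design_matrix(s, basis=basis)
        sp = oe.simulate_spikes(s, nrn, seed=seed, basis=basis)
        theta = nrn.theta_vector(d.variables, basis.n_basis)
        fit = oe.GLMFit(theta=theta, variables=d.variables,
                        n_basis=basis.n_basis, xi=0.0, nll_train=0.0,
                        converged=True)
        r2_single.append(r2_heldout(fit, sp.binned_counts, d,
                                    np.arange(s.n_trials)))
        pred = predict_rate(theta, d.X).reshape(s.n_trials, -1)
        psth_pred = smooth_boxcar(pred.mean(axis=0))
        psth_obs = smooth_boxcar(sp.binned_counts.mean(axis=0))
        ss_res = np.sum((psth_obs - psth_pred) ** 2)
        ss_tot = np.sum((psth_obs - psth_obs.mean()) ** 2)
        r2_psth.append(1 - ss_res / ss_tot)
    assert all(r > 0 for r in r2_single)
    assert r2_psth[1] > r2_psth[0]


def test_predicted_psth_matches_empirical(archetype_fits, archetype_spikes,
                                          design):
    # mirror of the fitted-model PSTH check: trial-averaged prediction
    # explains the empirical PSTH for task-modulated archetypes
    for idx in (0, 2, 3, 4):
        fit, sp = archetype_fits[idx], archetype_spikes[idx]
        pred = predict_rate(fit.theta, design.X).reshape(design.n_trials, -1)
        psth_pred = smooth_boxcar(pred.mean(axis=0))
        psth_obs = smooth_boxcar(sp.binned_counts.mean(axis=0))
        ss_res = np.sum((psth_obs - psth_pred) ** 2)
        ss_tot = np.sum((psth_obs - psth_obs.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.5


def test_compare_variants_identical_and_shifted():
    rng = np.random.default_rng(0)
    base = rng.normal(1000, 10, size=20)
    table = pd.DataFrame({"a": base, "b": base})
    res = oe.compare_variants(table)
    row = res[(res.variant_a == "a") & (res.variant_b == "b")].iloc[0]
    assert row.p == 1.0 and row.median_diff == 0.0

    table = pd.DataFrame({"a": base, "b": base + 1.0})
    res = oe.compare_variants(table)
    ab = res[(res.variant_a == "a") & (res.variant_b == "b")].iloc[0]
    ba = res[(res.variant_a == "b") & (res.variant_b == "a")].iloc[0]
    assert ab.p < 0.01
    assert ab.median_diff == pytest.approx(-1.0)
    assert ba.median_diff == pytest.approx(1.0)
    assert ab.p == pytest.approx(ba.p)


def test_compare_variants_needs_six_pairs():
    table = pd.DataFrame({"a": np.arange(5.0), "b": np.arange(5.0) + 1})
    with pytest.raises(ValueError):
        oe.compare_variants(table)


def test_smooth_boxcar_matches_shrinking_window():
    x = np.arange(10.0)
    sm = smooth_boxcar(x, width=5)
    assert sm[0] == x[0]
    assert sm[1] == pytest.approx(x[:3].mean())
    assert sm[4] == pytest.approx(x[2:7].mean())
    assert sm[-1] == x[-1]
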
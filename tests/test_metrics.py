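"""Encoding metrics: reduced designs, CPD, MI, d-prime, cluster averages."""

import numpy as np
import pytest
import scipy.stats

import ofc_encoding as oe
from ofc_encoding import metrics as M
from ofc_encoding.glm import predict_rate
from ofc_encoding.task import GroundTruthNeuron, SpikeData


def test_reduced_design_halves_streams(design, session):
    red = M.reduced_design(design, "reward")
    jw = design.variables.index("win")
    jl = design.variables.index("loss")
    for i, tr in enumerate(session):
        if tr.outcome == "win":
            b = np.argmax(design.streams[i, :, jw])
            assert red.streams[i, b, jw] == pytest.approx(0.5)
            assert red.streams[i, b, jl] == pytest.approx(0.5)
            break


def test_reduced_design_conserves_mass(design):
    for group in ("reward", "rewardHistory", "choice", "clicks", "flashes"):
        red = M.reduced_design(design, group)
        members = [m for m in M.COVARIATE_GROUPS[group]
                   if m in design.variables]
        idx = [design.variables.index(m) for m in members]
        assert np.allclose(design.streams[:, :, idx].sum(),
                           red.streams[:, :, idx].sum())
    with pytest.raises(KeyError):
        M.reduced_design(design, "bogus")


def test_singleton_group_cpd_is_exactly_zero(archetype_fits, archetype_spikes,
                                             design, session):
    M.COVARIATE_GROUPS["winOnly"] = ("win",)
    M.GROUP_ALIGNMENT["winOnly"] = "t_choice"
    try:
        # averaging a single member leaves the design unchanged
        red = M.reduced_design(design, "winOnly")
        assert np.array_equal(red.X, design.X)
        fit, sp = archetype_fits[4], archetype_spikes[4]
        lam_f = predict_rate(fit.theta, design.X)
        lam_r = predict_rate(fit.theta, red.X)
        assert np.array_equal(lam_f, lam_r)
    finally:
        del M.COVARIATE_GROUPS["winOnly"]
        del M.GROUP_ALIGNMENT["winOnly"]


def test_cpd_null_calibration_band(session, design, null_spikes):
    # planted-null: no reward-history kernels at all -> rejection near 5%
    fit = oe.fit_glm(null_spikes.binned_counts, design, xi=1.0)
    fracs = []
    for seed in range(3):
        ms = M.cpd(fit, design, null_spikes.binned_counts, session,
                   "rewardHistory", n_shuffles=200, seed=seed)
        fracs.append(float(ms.significant.mean()))
    assert 0.0 <= np.mean(fracs) < 0.12


def test_cpd_planted_positive_trial_start_and_prechoice(
        archetype_fits, archetype_spikes, design, session):
    fit, sp = archetype_fits[2], archetype_spikes[2]
    ms = M.cpd(fit, design, sp.binned_counts, session, "rewardHistory",
               n_shuffles=200, seed=0, outlier_threshold=np.inf)
    t = ms.time
    start = (t > -0.25) & (t < 1.0)
    prechoice = (t > 1.5) & (t < 3.5)
    assert ms.significant[start].any()
    assert ms.significant[prechoice].any()
    # values are null-mean-subtracted
    assert np.allclose(ms.values, ms.raw - ms.null_mean)


def test_cpd_zero_history_archetype_not_significant(
        archetype_fits, archetype_spikes, design, session):
    # reward_locked carries equal history kernels (no differential)
    fit, sp = archetype_fits[4], archetype_spikes[4]
    ms = M.cpd(fit, design, sp.binned_counts, session, "rewardHistory",
               n_shuffles=200, seed=0)
    assert ms.significant.mean() < 0.15


def test_cpd_monotone_in_planted_amplitude(session, design, basis):
    meds = []
    for amp in (0.4, 1.0):
        kw = {"prevWin": amp * np.array([0.5, 0, 0.7, 0.7, 0, 0, 0, 0.9, 0.9]),
              "prevLoss": np.zeros(9)}
        nrn = GroundTruthNeuron(archetype="a3", kernel_weights=kw,
                                background=float(np.log(0.25)), unit_id="a")
        sp = oe.simulate_spikes(session, nrn, seed=70, basis=basis)
        fit = oe.fit_glm(sp.binned_counts, design, xi=1.0)
        ms = M.cpd(fit, design, sp.binned_counts, session, "rewardHistory",
                   n_shuffles=100, seed=0, outlier_threshold=np.inf)
        meds.append(np.max(ms.raw))
    assert meds[1] > meds[0]


def test_cpd_alignment_to_port_exit(archetype_fits, archetype_spikes, design,
                                    session):
    fit, sp = archetype_fits[2], archetype_spikes[2]
    ms = M.cpd(fit, design, sp.binned_counts, session, "rewardHistory",
               n_shuffles=50, seed=0, align="t_exit_center",
               align_window=(-4.0, 4.0), outlier_threshold=np.inf)
    assert ms.alignment == "t_exit_center"
    assert len(ms.time) == 160
    assert ms.time[0] == pytest.approx(-4.0 + 0.025)
    # history re-emergence just before port exit
    pre = (ms.time > -1.0) & (ms.time < 0.0)
    assert ms.significant[pre].any()


def test_mi_requires_event_group_and_cov(archetype_fits, design, session):
    with pytest.raises(ValueError):
        M.mutual_information(archetype_fits[0], design, session, "clicks")
    fit_nocov = oe.GLMFit(theta=archetype_fits[0].theta,
                          variables=design.variables, n_basis=9, xi=1.0,
                          nll_train=0.0, converged=True)
    with pytest.raises(ValueError):
        M.mutual_information(fit_nocov, design, session, "reward")


def test_mi_bounded_by_stimulus_entropy(archetype_fits, design, session):
    fit = archetype_fits[2]
    ms = M.mutual_information(fit, design, session, "rewardHistory",
                              n_samples=200, n_shuffles=100, seed=0)
    assert np.all(ms.raw >= 0.0)
    assert np.all(ms.raw <= ms.extras["H_x"] + 1e-9)


def test_mi_matches_exact_enumeration_oracle(session, design, basis,
                                             archetype_neurons):
    # deterministic parameters (negligible covariance): the sampled MI must
    # agree with exact enumeration over the Poisson mixture on counts 0..10
    nrn = archetype_neurons[2]
    theta = nrn.theta_vector(design.variables, basis.n_basis)
    n_par = len(theta)
    fit = oe.GLMFit(theta=theta, variables=design.variables,
                    n_basis=basis.n_basis, xi=0.0, nll_train=0.0,
                    converged=True, kernel_cov=1e-18 * np.eye(n_par))
    ms = M.mutual_information(fit, design, session, "rewardHistory",
                              n_samples=1500, n_shuffles=10, seed=0)

    # exact oracle
    lam = predict_rate(theta, design.X).reshape(design.n_trials, -1)
    conds = M._trial_conditions(session, "rewardHistory")
    trials = np.array([i for i, c in enumerate(conds) if c is not None])
    members = sorted({conds[i] for i in trials})
    ys = np.arange(11)
    exact = np.empty(design.n_bins)
    for t in range(design.n_bins):
        pk, pyk = [], []
        for m in members:
            idx = [i for i in trials if conds[i] == m]
            if not idx:
                continue
            pmf = scipy.stats.poisson.pmf(ys[None, :10], lam[idx, t][:, None])
            tail = 1.0 - pmf.sum(axis=1, keepdims=True)
            p = np.hstack([pmf, np.maximum(tail, 0)]).mean(axis=0)
            pk.append(len(idx))
            pyk.append(p)
        pk = np.array(pk, float) / sum(pk)
        pyk = np.array(pyk)
        pm = pk @ pyk
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pyk > 0, np.log(np.maximum(pyk, 1e-300) /
                                             np.maximum(pm, 1e-300)), 0.0)
        exact[t] = max((pk[:, None] * pyk * ratio).sum(), 0.0) / np.log(2)

    assert np.max(np.abs(ms.raw - exact)) < 0.03
    assert np.corrcoef(ms.raw, exact)[0, 1] > 0.97


def _fake_spikes(session, rates_hz, dt=0.05, n_bins=160):
    counts = rates_hz * dt
    edges = -2.0 + np.arange(n_bins + 1) * dt
    return SpikeData(unit_id="fake", spike_times=[np.empty(0)] * len(rates_hz),
                     binned_counts=counts, bin_edges=edges)


def test_dprime_analytic_oracle():
    cfg = oe.TaskConfig(n_trials=600, probability_levels=(0.0, 1.0),
                        p_opt_out=0.0, seed=20)
    s = oe.generate_session(cfg, seed=20)
    prev = np.array([tr.prev_outcome for tr in s.trials])
    rng = np.random.default_rng(21)
    rates = np.where((prev == "win")[:, None],
                     rng.normal(14.0, 2.0, (s.n_trials, 160)),
                     rng.normal(10.0, 2.0, (s.n_trials, 160)))
    dp = M.dprime(_fake_spikes(s, rates), s, n_shuffles=100, seed=0,
                  smooth_bins=1)
    assert dp.raw.mean() == pytest.approx(2.0, abs=0.1)


def test_dprime_null_is_calibrated(session, null_spikes):
    dp = M.dprime(null_spikes, session, n_shuffles=200, seed=3)
    assert abs(dp.values.mean()) < 0.1      # corrected d' centers on zero
    assert dp.significant.mean() < 0.15


def test_dprime_planted_archetype(archetype_spikes, session):
    dp = M.dprime(archetype_spikes[2], session, n_shuffles=200, seed=0)
    t = dp.time
    assert dp.significant[(t > 1.5) & (t < 3.5)].any()
    dp0 = M.dprime(archetype_spikes[4], session, n_shuffles=200, seed=0)
    assert dp.significant.mean() > dp0.significant.mean()


def test_dprime_requires_both_conditions():
    cfg = oe.TaskConfig(n_trials=30, probability_levels=(1.0,), p_opt_out=0.0,
                        seed=22)
    s = oe.generate_session(cfg, seed=22)  # all wins -> no prevLoss trials
    rates = np.ones((30, 160))
    with pytest.raises(ValueError):
        M.dprime(_fake_spikes(s, rates), s, n_shuffles=10, seed=0)


def _toy_series(values, significant, outlier=False):
    n = len(values)
    return M.MetricSeries(name="cpd", group="g", time=np.arange(n),
                          values=np.asarray(values, float),
                          raw=np.asarray(values, float),
                          null_mean=np.zeros(n), null_ci95=np.zeros(n),
                          significant=np.asarray(significant, bool),
                          outlier=outlier)


def test_cluster_average_rules():
    m1 = _toy_series([1.0, 2.0], [True, False])
    m2 = _toy_series([3.0, 4.0], [True, True])
    m3 = _toy_series([9.0, 9.0], [True, True], outlier=True)
    out = M.cluster_average([m1, m2, m3], np.array([1, 1, 1]))
    mean, sem = out[1]
    # outlier dropped; non-significant bins zeroed
    assert np.allclose(mean, [2.0, 2.0])
    assert np.all(np.isfinite(sem))
    # permutation invariance
    out2 = M.cluster_average([m2, m3, m1], np.array([1, 1, 1]))
    assert np.allclose(out2[1][0], mean)
    # singleton cluster: SEM undefined
    out3 = M.cluster_average([m1], np.array([2]))
    assert np.all(np.isnan(out3[2][1]))
    with pytest.raises(ValueError):
        M.cluster_average([m1, m2], np.array([1]))
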
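"""Epoch-rate regressions: recovery oracles, null calibration, and the
adaptive-value-coding classification rule."""

import numpy as np
import pytest

import ofc_encoding as oe
from ofc_encoding import regressions as R


@pytest.fixture(scope="module")
def reg_session():
    cfg = oe.TaskConfig(n_trials=300, p_opt_out=0.0, seed=33)
    return oe.generate_session(cfg, seed=33)


def _codes(session):
    win = np.array([1.0 if t.outcome == "win" else -1.0
                    for t in session.trials])
    choice = np.array([1.0 if t.choice == "left" else -1.0
                       for t in session.trials])
    vol = np.array([t.V_rewarded for t in session.trials])
    return win, choice, vol


def _rates(session, values, noise, seed):
    rng = np.random.default_rng(seed)
    r = values + rng.normal(0, noise, session.n_trials)
    return R.EpochRates(r=r, epoch="post_choice", window=(0, 1),
                        align="t_choice")


def test_history_regression_recovers_planted_lag(reg_session):
    win, _, _ = _codes(reg_session)
    prev1 = np.roll(win, 1)
    prev1[0] = 0.0
    rates = _rates(reg_session, 10.0 + 2.0 * prev1, 1.0, 0)
    res = R.history_regression(rates, reg_session)
    se = res.model.bse["winloss_n-1"]
    assert abs(res.coefficients["winloss_n-1"] - 2.0) < 3 * se
    for lag in range(2, 6):
        c = res.coefficients[f"winloss_n-{lag}"]
        assert abs(c) < 3 * res.model.bse[f"winloss_n-{lag}"] + 0.2


def test_history_regression_sign_flip_linearity(reg_session):
    rng = np.random.default_rng(1)
    rates = R.EpochRates(r=rng.normal(10, 2, reg_session.n_trials),
                         epoch="post_choice", window=(0, 1), align="t_choice")
    res = R.history_regression(rates, reg_session)
    flipped = oe.generate_session(reg_session.config, seed=33)
    for tr in flipped.trials:  # swap win/loss labels everywhere
        tr.outcome = {"win": "loss", "loss": "win"}[tr.outcome]
        tr.prev_outcome = {"win": "loss", "loss": "win",
                           "none": "none"}[tr.prev_outcome]
    res_f = R.history_regression(rates, flipped)
    for lag in range(1, 6):
        assert res_f.coefficients[f"winloss_n-{lag}"] == pytest.approx(
            -res.coefficients[f"winloss_n-{lag}"], abs=1e-9)


def test_history_null_calibration(reg_session):
    hits = np.zeros(5)
    n_sim = 200
    rng = np.random.default_rng(2)
    for s in range(n_sim):
        rates = R.EpochRates(r=rng.normal(10, 2, reg_session.n_trials),
                             epoch="post_choice", window=(0, 1),
                             align="t_choice")
        res = R.history_regression(rates, reg_session)
        for lag in range(1, 6):
            hits[lag - 1] += res.pvalues[f"winloss_n-{lag}"] < 0.05
    rate = hits.sum() / (5 * n_sim)
    assert 0.03 < rate < 0.07


def test_outcome_adaptation_classifications(reg_session):
    win, _, _ = _codes(reg_session)
    prev = np.roll(win, 1)
    prev[0] = 0.0
    adaptive = _rates(reg_session, 8 + 3 * win - 1.5 * prev, 1.0, 3)
    assert R.outcome_adaptation_regression(
        adaptive, reg_session).classification == "adaptive"
    nonadaptive = _rates(reg_session, 8 + 3 * win + 1.5 * prev, 1.0, 4)
    assert R.outcome_adaptation_regression(
        nonadaptive, reg_session).classification == "modulated-non-adaptive"
    flat = _rates(reg_session, np.full(reg_session.n_trials, 8.0), 1.0, 5)
    assert R.outcome_adaptation_regression(
        flat, reg_session).classification == "not-significant"


def test_classification_invariant_to_rate_rescaling(reg_session):
    win, _, _ = _codes(reg_session)
    prev = np.roll(win, 1)
    prev[0] = 0.0
    r = 8 + 3 * win - 1.5 * prev + np.random.default_rng(6).normal(
        0, 1, reg_session.n_trials)
    a = R.EpochRates(r=r, epoch="post_choice", window=(0, 1), align="t_choice")
    b = R.EpochRates(r=r * 0.05, epoch="post_choice", window=(0, 1),
                     align="t_choice")  # Hz -> spikes/bin
    assert (R.outcome_adaptation_regression(a, reg_session).classification ==
            R.outcome_adaptation_regression(b, reg_session).classification)


def test_volume_adaptation_classifications(reg_session):
    win, _, vol = _codes(reg_session)
    prev = np.roll(win, 1)
    prev[0] = 0.0
    adaptive = _rates(reg_session, 5 + 0.1 * vol - 0.8 * prev, 1.0, 7)
    res = R.volume_adaptation_regression(adaptive, reg_session)
    assert res.classification == "adaptive"
    se = res.model.bse["vol"]
    assert abs(res.coefficients["vol"] - 0.1) < 3 * se
    nonadaptive = _rates(reg_session, 5 + 0.1 * vol + 0.8 * prev, 1.0, 8)
    assert R.volume_adaptation_regression(
        nonadaptive, reg_session).classification == "modulated-non-adaptive"


def test_volume_shuffled_is_null(reg_session):
    rng = np.random.default_rng(9)
    _, _, vol = _codes(reg_session)
    hits = 0
    n_sim = 200
    for s in range(n_sim):
        shuffled_vol = rng.permutation(vol)
        rates = _rates(reg_session, 5 + 0.1 * shuffled_vol, 1.0, 100 + s)
        # rates built from shuffled volumes are independent of true volumes
        res = R.volume_adaptation_regression(rates, reg_session)
        hits += res.pvalues["vol"] < 0.05
    assert hits / n_sim < 0.10


def test_rpe_regression_recovery_and_null(reg_session):
    rpe = np.array([t.rpe for t in reg_session.trials])
    rates = _rates(reg_session, 6 + 0.2 * rpe, 1.0, 10)
    res = R.rpe_regression(rates, reg_session)
    assert abs(res.coefficients["rpe"] - 0.2) < 3 * res.model.bse["rpe"]
    flat = _rates(reg_session, np.full(reg_session.n_trials, 6.0), 1.0, 11)
    assert R.rpe_regression(flat, reg_session).pvalues["rpe"] >= 0.0


def test_rpe_degenerate_all_safe_session():
    cfg = oe.TaskConfig(n_trials=60, probability_levels=(1.0,), p_opt_out=0.0,
                        seed=12)
    s = oe.generate_session(cfg, seed=12)  # every trial a safe win: RPE = 0
    rates = R.EpochRates(r=np.random.default_rng(0).normal(5, 1, 60),
                         epoch="post_choice", window=(0, 1), align="t_choice")
    with pytest.raises(ValueError):
        R.rpe_regression(rates, s)


def test_coefficient_bias_small_at_300_trials(reg_session):
    win, choice, vol = _codes(reg_session)
    prev = np.roll(win, 1)
    prev[0] = 0.0
    ests = []
    for s in range(30):
        rates = _rates(reg_session, 8 + 3 * win - 1.5 * prev + 0.5 * choice,
                       1.0, 200 + s)
        res = R.outcome_adaptation_regression(rates, reg_session)
        ests.append([res.coefficients["winloss"], res.coefficients["rewhist"],
                     res.coefficients["choice"]])
    mean = np.mean(ests, axis=0)
    for est, true in zip(mean, (3.0, -1.5, 0.5)):
        assert abs(est - true) < 0.05 * abs(true) + 0.02


def test_epoch_rates_window(archetype_spikes, session):
    er = R.epoch_rates(archetype_spikes[4], session, epoch="post_choice")
    assert er.r.shape == (session.n_trials,)
    assert np.all(er.r >= 0)
    with pytest.raises(ValueError):
        R.epoch_rates(archetype_spikes[4], session, epoch="bogus")


def test_cluster_enrichment_planted_and_uniform():
    rng = np.random.default_rng(13)
    labels = np.repeat(np.arange(1, 6), 40)
    # uniform planting: all CIs overlap all point estimates
    cls = np.where(rng.random(200) < 0.3, "adaptive", "not-significant")
    res = R.cluster_enrichment(cls, labels)
    for c in range(1, 6):
        lo, hi = res.ci95[c]
        for c2 in range(1, 6):
            assert lo <= res.probability[c2] + 0.25
    # concentrated planting: cluster 1 excludes the others' estimates
    cls2 = np.array(["not-significant"] * 200, dtype=object)
    cls2[labels == 1] = "adaptive"
    res2 = R.cluster_enrichment(cls2, labels)
    lo1, hi1 = res2.ci95[1]
    assert all(res2.probability[c] < lo1 for c in range(2, 6))
    # zero hits: exact lower bound at 0
    assert res2.ci95[2][0] == 0.0
    assert res2.probability[2] == 0.0


def test_enrichment_input_validation():
    with pytest.raises(ValueError):
        R.cluster_enrichment(["adaptive"], np.array([1, 2]))
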
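"""Trial-history and adaptive-value-coding regressions on epoch rates.

Single-trial firing rates averaged over a named epoch (post-choice:
1 s after reward onset; pre-choice: a configurable window before
side-port entry) are regressed on outcome, history, choice, volume and
reward-prediction-error regressors.  A unit is classified *adaptive*
when its current- and previous-reward coefficients are both significant
with opposite signs (reward responses rescaled against recent history),
*modulated non-adaptive* when both are significant with the same sign,
and *not significant* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import beta as beta_dist

from .task import Session, SpikeData

__all__ = [
    "EpochRates", "RegressionResult", "EnrichmentResult",
    "epoch_rates", "history_regression", "outcome_adaptation_regression",
    "volume_adaptation_regression", "rpe_regression", "cluster_enrichment",
]


@dataclass
class EpochRates:
    """Per-trial firing rate (Hz) averaged over one epoch."""

    r: np.ndarray              # one value per trial in the session
    epoch: str
    window: Tuple[float, float]
    align: str


@dataclass
class RegressionResult:
    coefficients: Dict[str, float]
    pvalues: Dict[str, float]
    model_p: float
    classification: str        # adaptive | modulated-non-adaptive | not-significant
    n_trials: int
    model: object = field(default=None, repr=False)


@dataclass
class EnrichmentResult:
    probability: Dict[int, float]
    ci95: Dict[int, Tuple[float, float]]
    counts: Dict[int, Tuple[int, int]]   # (hits, n)


def epoch_rates(
    spikes: SpikeData,
    session: Session,
    epoch: str = "post_choice",
    window: Optional[Tuple[float, float]] = None,
    align: Optional[str] = None,
) -> EpochRates:
    """Average firing rate per trial over a named epoch.

    ``post_choice`` uses [0, 1] s after reward onset (side-port entry);
    ``pre_choice`` uses [-1, 0] s before side-port entry.  Custom epochs
    pass ``window`` and ``align`` explicitly.
    """
    presets = {"post_choice": ((0.0, 1.0), "t_choice"),
               "pre_choice": ((-1.0, 0.0), "t_choice")}
    if window is None or align is None:
        if epoch not in presets:
            raise ValueError(f"unknown epoch {epoch!r}; pass window and align")
        window, align = presets[epoch]
    r = np.empty(session.n_trials)
    for i, tr in enumerate(session.trials):
        t0 = getattr(tr, align) - tr.t_start + window[0]
        t1 = getattr(tr, align) - tr.t_start + window[1]
        st = spikes.spike_times[i]
        r[i] = np.sum((st >= t0) & (st < t1)) / (t1 - t0)
    return EpochRates(r=r, epoch=epoch, window=window, align=align)


def _pm1(flag: bool) -> float:
    return 1.0 if flag else -1.0


def _fit_ols(r: np.ndarray, X: pd.DataFrame) -> sm.regression.linear_model.RegressionResultsWrapper:
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("collinear regression design (constant regressor?)")
    return sm.OLS(r, X).fit()


def _classify(res, target_a: str, target_b: str, alpha: float = 0.05) -> str:
    pa, pb = res.pvalues[target_a], res.pvalues[target_b]
    if pa < alpha and pb < alpha:
        same = np.sign(res.params[target_a]) == np.sign(res.params[target_b])
        return "modulated-non-adaptive" if same else "adaptive"
    return "not-significant"


def _result(res, classification: str, n: int) -> RegressionResult:
    return RegressionResult(
        coefficients={k: float(v) for k, v in res.params.items()},
        pvalues={k: float(v) for k, v in res.pvalues.items()},
        model_p=float(res.f_pvalue), classification=classification,
        n_trials=n, model=res)


def history_regression(rates: EpochRates, session: Session,
                       n_back: int = 5) -> RegressionResult:
    """Regression of epoch rates on win/loss outcomes 1..n_back trials back.

    Outcomes are coded +1 (win) / -1 (loss); a previous opt-out is coded 0.
    Includes a fitted choice coefficient and intercept; trials whose own
    outcome is an opt-out, and the first ``n_back`` trials, are excluded.
    """
    rows, y = [], []
    for i, tr in enumerate(session.trials):
        if i < n_back or tr.outcome == "opt_out":
            continue
        row = {"choice": _pm1(tr.choice == "left")}
        for lag in range(1, n_back + 1):
            out = session.trials[i - lag].outcome
            row[f"winloss_n-{lag}"] = (0.0 if out == "opt_out"
                                       else _pm1(out == "win"))
        rows.append(row)
        y.append(rates.r[i])
    if len(rows) < n_back + 3:
        raise ValueError("too few usable trials with full history")
    res = _fit_ols(np.asarray(y), pd.DataFrame(rows))
    cls = ("not-significant" if res.f_pvalue >= 0.05 else "modulated")
    return _result(res, cls, len(rows))


def _adaptation_frame(session: Session):
    idx, rows = [], []
    for i, tr in enumerate(session.trials):
        if i == 0 or tr.outcome == "opt_out":
            continue
        prev = session.trials[i - 1].outcome
        if prev == "opt_out":
            continue
        idx.append(i)
        rows.append({
            "winloss": _pm1(tr.outcome == "win"),
            "rewhist": _pm1(prev == "win"),
            "choice": _pm1(tr.choice == "left"),
            "vol": tr.V_rewarded,
            "loss": 1.0 if tr.outcome == "loss" else 0.0,
            "rpe": tr.rpe,
        })
    return np.asarray(idx), pd.DataFrame(rows)


def outcome_adaptation_regression(rates: EpochRates,
                                  session: Session) -> RegressionResult:
    """Post-choice rates ~ current win/loss + previous win/loss + choice."""
    idx, F = _adaptation_frame(session)
    if len(idx) < 20:
        raise ValueError("fewer than 20 usable trials")
    res = _fit_ols(rates.r[idx], F[["winloss", "rewhist", "choice"]])
    return _result(res, _classify(res, "winloss", "rewhist"), len(idx))


def volume_adaptation_regression(rates: EpochRates,
                                 session: Session) -> RegressionResult:
    """Post-choice rates ~ rewarded volume + loss + previous win/loss + choice."""
    idx, F = _adaptation_frame(session)
    if len(idx) < 20:
        raise ValueError("fewer than 20 usable trials")
    res = _fit_ols(rates.r[idx], F[["vol", "loss", "rewhist", "choice"]])
    return _result(res, _classify(res, "vol", "rewhist"), len(idx))


def rpe_regression(rates: EpochRates, session: Session) -> RegressionResult:
    """Post-choice rates ~ reward prediction error + choice.

    RPE = rewarded volume minus the chosen option's expected value (p * V).
    """
    idx, F = _adaptation_frame(session)
    if len(idx) < 20:
        raise ValueError("fewer than 20 usable trials")
    if np.allclose(F["rpe"].to_numpy().std(), 0.0):
        raise ValueError("zero-variance RPE (all-safe, all-win session)")
    res = _fit_ols(rates.r[idx], F[["rpe", "choice"]])
    cls = "modulated" if res.pvalues["rpe"] < 0.05 else "not-significant"
    return _result(res, cls, len(idx))


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def cluster_enrichment(classifications: Sequence[str],
                       labels: np.ndarray,
                       target: str = "adaptive") -> EnrichmentResult:
    """Per-cluster probability of a classification with exact binomial CIs.

    Enrichment is read off by CI comparison: a cluster is preferentially
    enriched only if its interval excludes the other clusters' point
    estimates.
    """
    labels = np.asarray(labels)
    if len(labels) != len(classifications):
        raise ValueError("one classification per labeled neuron required")
    prob, ci, counts = {}, {}, {}
    for c in np.unique(labels):
        mask = labels == c
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"empty cluster {c}")
        k = int(sum(cl == target for cl, m in zip(classifications, mask) if m))
        prob[int(c)] = k / n
        ci[int(c)] = _clopper_pearson(k, n)
        counts[int(c)] = (k, n)
    return EnrichmentResult(probability=prob, ci95=ci, counts=counts)
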
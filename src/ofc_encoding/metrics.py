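"""Per-neuron encoding metrics: CPD, mutual information, and d-prime.

CPD (coefficient of partial determination) measures the percent of
trial-summed squared error uniquely attributable to a covariate group by
comparing the full model against a reduced model in which the group's
condition identity is erased (member streams replaced by their mean, so
the event response survives with the condition-averaged kernel).  MI
relates trial-level conditions to spike counts through a doubly
stochastic sampling of the fitted parameter distribution.  d' contrasts
previous-win and previous-loss firing rates per time bin.  All three are
reported with shuffle nulls and significance masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .design import DesignMatrix
from .glm import GLMFit, predict_rate, smooth_boxcar
from .task import Session, SpikeData

__all__ = [
    "COVARIATE_GROUPS", "MetricSeries",
    "reduced_design", "cpd", "mutual_information", "dprime",
    "cluster_average",
]

#: covariate groups whose joint omission defines each CPD/MI contrast
COVARIATE_GROUPS: Dict[str, Tuple[str, ...]] = {
    "reward": ("win", "loss"),
    "rewardHistory": ("prevWin", "prevLoss", "prevOptOut"),
    "choice": ("leftChoice", "rightChoice"),
    "clicks": ("leftClick", "rightClick"),
    "flashes": ("leftFlash", "rightFlash"),
}

#: groups with one event per trial whose condition labels can be shuffled
_EVENT_GROUPS = ("reward", "rewardHistory", "choice")

#: reporting alignment per group
GROUP_ALIGNMENT = {
    "reward": "t_choice", "rewardHistory": "t_start",
    "choice": "t_exit_center", "clicks": "t_start", "flashes": "t_start",
}


@dataclass
class MetricSeries:
    """One neuron's per-time-bin metric with its shuffle null."""

    name: str
    group: str
    time: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)       # null-mean-subtracted
    raw: np.ndarray = field(repr=False)
    null_mean: np.ndarray = field(repr=False)
    null_ci95: np.ndarray = field(repr=False)    # one-sided 95th percentile
    significant: np.ndarray = field(repr=False)
    n_shuffles: int = 0
    alignment: str = "t_start"
    outlier: bool = False
    extras: dict = field(default_factory=dict)


def reduced_design(design: DesignMatrix, group: str) -> DesignMatrix:
    """Replace each member's regressors by the member mean (no refit).

    Event timing is preserved while condition identity is erased: under
    the original weights the prediction uses the condition-averaged
    kernel at each trial's own event times.  All other covariates are
    untouched.
    """
    if group not in COVARIATE_GROUPS:
        raise KeyError(f"unknown covariate group: {group!r}")
    members = [m for m in COVARIATE_GROUPS[group] if m in design.variables]
    X = design.X.copy()
    streams = design.streams.copy()
    blocks = [X[:, design.var_slice(m)] for m in members]
    mean_block = np.mean(blocks, axis=0)
    svars = [design.variables.index(m) for m in members]
    mean_stream = streams[:, :, svars].mean(axis=2)
    for m, j in zip(members, svars):
        X[:, design.var_slice(m)] = mean_block
        streams[:, :, j] = mean_stream
    return replace(design, X=X, streams=streams)


def _group_members(design: DesignMatrix, group: str) -> List[str]:
    return [m for m in COVARIATE_GROUPS[group] if m in design.variables]


def _trial_conditions(session: Session, group: str) -> List[Optional[str]]:
    """Per-trial condition (member name) for an event group; None = excluded."""
    conds: List[Optional[str]] = []
    for tr in session.trials:
        if group == "reward":
            conds.append(tr.outcome if tr.outcome in ("win", "loss") else None)
        elif group == "rewardHistory":
            conds.append({"win": "prevWin", "loss": "prevLoss",
                          "opt_out": "prevOptOut"}.get(tr.prev_outcome))
        elif group == "choice":
            conds.append(tr.choice + "Choice")
        else:
            raise KeyError(group)
    return conds


def _condition_weights(cond_idx: np.ndarray, n_members: int) -> np.ndarray:
    """Per-trial weights 1/n_condition so each condition contributes equally."""
    counts = np.bincount(cond_idx, minlength=n_members).astype(float)
    counts[counts == 0] = 1.0
    return 1.0 / counts[cond_idx]


def _gather_indices(session: Session, trials: np.ndarray,
                    design: DesignMatrix, align: str,
                    out_window: Tuple[float, float]
                    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial source-bin indices mapping the native grid onto a grid
    aligned to ``align`` (valid mask marks bins inside the native window)."""
    dt = design.basis.dt
    n_out = int(round((out_window[1] - out_window[0]) / dt))
    src = np.empty((len(trials), n_out), dtype=int)
    for r, i in enumerate(trials):
        tr = session.trials[i]
        anchor = getattr(tr, align) - tr.t_start
        shift = int(np.floor((anchor + out_window[0] - design.window[0]) / dt))
        src[r] = shift + np.arange(n_out)
    valid = (src >= 0) & (src < design.n_bins)
    time = out_window[0] + (np.arange(n_out) + 0.5) * dt
    return np.clip(src, 0, design.n_bins - 1), valid, time


def cpd(
    fit: GLMFit,
    design: DesignMatrix,
    counts: np.ndarray,
    session: Session,
    group: str,
    n_shuffles: int = 500,
    seed: int = 0,
    align: Optional[str] = None,
    align_window: Tuple[float, float] = (-4.0, 4.0),
    weighting: bool = True,
    smooth_bins: int = 5,
    outlier_threshold: float = 0.5,
) -> MetricSeries:
    """Coefficient of partial determination (%) per time bin.

    ``CPD_t = (SSE_reduced - SSE_full) / SSE_reduced * 100`` with SSE taken
    across trials per bin; for the event groups (reward, reward history,
    choice) trial types are weighted so each condition contributes equally,
    and the shuffle null permutes condition labels across trials while
    keeping event timing fixed.  For clicks/flashes the null swaps the
    left/right kernel assignment on a random half of trials.  Values are
    null-mean-subtracted; bins inside the one-sided 95% band are flagged
    non-significant.  Units whose raw CPD exceeds ``outlier_threshold``
    anywhere are flagged as outliers for cluster averaging.
    """
    if group not in COVARIATE_GROUPS:
        raise KeyError(f"unknown covariate group: {group!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]).spawn(1)[0])
    y = np.asarray(counts, float).reshape(design.n_trials, design.n_bins)
    T = design.n_bins
    members = _group_members(design, group)

    lam_full = predict_rate(fit.theta, design.X).reshape(design.n_trials, T)
    lam_red = predict_rate(fit.theta, reduced_design(design, group).X
                           ).reshape(design.n_trials, T)

    # per-trial log-rate contribution of the group, and what it would be
    # under each alternative condition assignment
    eta_full = np.log(lam_full)
    if group in _EVENT_GROUPS:
        conds = _trial_conditions(session, group)
        trials = np.array([i for i, c in enumerate(conds) if c is not None])
        member_of = {m: k for k, m in enumerate(members)}
        cond_idx = np.array([member_of[conds[i]] for i in trials])
        # response templates: active member's convolved impulse block dotted
        # with each candidate condition's weights
        resp_if = np.zeros((len(trials), len(members), T))
        for r, i in enumerate(trials):
            rows = slice(i * T, (i + 1) * T)
            blk = design.X[rows, design.var_slice(conds[i])]
            for c, m in enumerate(members):
                resp_if[r, c] = blk @ fit.weights(m)
        eta_rest = eta_full[trials] - resp_if[np.arange(len(trials)), cond_idx]
    else:
        trials = np.arange(design.n_trials)
        cond_idx = None
        mL, mR = members
        resp = np.zeros((len(trials), 4, T))  # LL, RR, LR, RL
        for r, i in enumerate(trials):
            rows = slice(i * T, (i + 1) * T)
            XL = design.X[rows, design.var_slice(mL)]
            XR = design.X[rows, design.var_slice(mR)]
            resp[r, 0] = XL @ fit.weights(mL)
            resp[r, 1] = XR @ fit.weights(mR)
            resp[r, 2] = XL @ fit.weights(mR)
            resp[r, 3] = XR @ fit.weights(mL)
        eta_rest = eta_full[trials] - resp[:, 0] - resp[:, 1]

    yg = y[trials]
    if weighting and group in _EVENT_GROUPS:
        w = _condition_weights(cond_idx, len(members))
    else:
        w = np.ones(len(trials))

    if align is not None and align != "t_start":
        src, valid, time = _gather_indices(session, trials, design, align,
                                           align_window)
    else:
        align = "t_start"
        src = np.tile(np.arange(T), (len(trials), 1))
        valid = np.ones_like(src, dtype=bool)
        time = design.time()

    err_red = np.take_along_axis((yg - lam_red[trials]) ** 2, src, axis=1)

    def cpd_curve(lam_f: np.ndarray, weights: np.ndarray) -> np.ndarray:
        err_f = np.take_along_axis((yg - lam_f) ** 2, src, axis=1)
        wv = weights[:, None] * valid
        sse_f = np.einsum("tb,tb->b", wv, err_f)
        sse_r = np.einsum("tb,tb->b", wv, err_red)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(sse_r > 0, (sse_r - sse_f) / np.maximum(sse_r, 1e-300),
                           0.0)
        return out * 100.0

    raw = cpd_curve(lam_full[trials], w)

    null = np.empty((n_shuffles, len(time)))
    for s in range(n_shuffles):
        if group in _EVENT_GROUPS:
            perm = rng.permutation(len(trials))
            shuf_idx = cond_idx[perm]
            lam_shuf = np.exp(eta_rest +
                              resp_if[np.arange(len(trials)), shuf_idx])
            w_s = (_condition_weights(shuf_idx, len(members))
                   if weighting else np.ones(len(trials)))
        else:
            swap = rng.permutation(len(trials)) < len(trials) // 2
            contrib = np.where(swap[:, None], resp[:, 2] + resp[:, 3],
                               resp[:, 0] + resp[:, 1])
            lam_shuf = np.exp(eta_rest + contrib)
            w_s = w
        null[s] = cpd_curve(lam_shuf, w_s)

    if smooth_bins and smooth_bins > 1:
        raw = smooth_boxcar(raw, width=smooth_bins)
        null = smooth_boxcar(null, width=smooth_bins, axis=-1)

    null_mean = null.mean(axis=0)
    ci95 = np.percentile(null, 95, axis=0)
    significant = raw > ci95
    values = raw - null_mean

    return MetricSeries(
        name="cpd", group=group, time=time, values=values, raw=raw,
        null_mean=null_mean, null_ci95=ci95, significant=significant,
        n_shuffles=n_shuffles, alignment=align,
        outlier=bool(np.nanmax(raw) > outlier_threshold),
        extras={"n_trials": len(trials)})


def mutual_information(
    fit: GLMFit,
    design: DesignMatrix,
    session: Session,
    group: str,
    n_samples: int = 500,
    n_shuffles: int = 500,
    seed: int = 0,
    max_count: int = 10,
    base: str = "bits",
) -> MetricSeries:
    """Sampling-based MI (bits) between spike counts and a covariate group.

    Per time bin, ``n_samples`` parameter vectors are drawn from the
    fit's normal parameter distribution (inverse-Hessian covariance),
    passed through the exponential link and Poisson spiking, truncated at
    ``max_count`` spikes per 50 ms bin; the conditional count distribution
    is the average over trials sharing a condition.  Restricted to the
    trial-level groups (reward, reward history, choice).
    """
    if group not in _EVENT_GROUPS:
        raise ValueError("MI is defined for the reward, rewardHistory and "
                         "choice groups only")
    if fit.kernel_cov is None:
        raise ValueError("fit must carry a kernel covariance (inverse Hessian)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]).spawn(1)[0])

    conds = _trial_conditions(session, group)
    trials = np.array([i for i, c in enumerate(conds) if c is not None])
    if len(trials) == 0:
        raise ValueError("no trials carry the requested conditions")
    members = _group_members(design, group)
    member_of = {m: k for k, m in enumerate(members)}
    cond_idx = np.array([member_of[conds[i]] for i in trials])
    counts_k = np.bincount(cond_idx, minlength=len(members))
    present = counts_k > 0
    if present.sum() < 2:
        raise ValueError("need at least two populated conditions for MI")
    p_x = counts_k[present] / counts_k.sum()
    H_x = float(-(p_x * np.log(p_x)).sum())

    # draw parameter samples once; per-bin rates follow from the design rows
    L = np.linalg.cholesky(fit.kernel_cov +
                           1e-12 * np.eye(fit.kernel_cov.shape[0]))
    theta_s = fit.theta[:, None] + L @ rng.standard_normal(
        (len(fit.theta), n_samples))

    T = design.n_bins
    n_tr = len(trials)
    hist = np.zeros((T, n_tr, max_count + 1))
    for t in range(T):
        rows = trials * T + t
        eta = design.X[rows] @ theta_s[:-1] + theta_s[-1]
        lam = np.exp(np.minimum(eta, 10.0))
        ys = np.minimum(rng.poisson(lam), max_count)
        for r in range(n_tr):
            hist[t, r] = np.bincount(ys[r], minlength=max_count + 1)
    hist /= n_samples

    cond_onehot = np.zeros((len(members), n_tr))
    cond_onehot[cond_idx, np.arange(n_tr)] = 1.0

    def mi_curve(onehot: np.ndarray) -> np.ndarray:
        nk = onehot.sum(axis=1)
        keep = nk > 0
        pk = nk[keep] / nk.sum()
        # p(y | x_k) per bin: average over trials in condition k
        p_cond = np.einsum("kr,trY->tkY", onehot[keep] / nk[keep, None], hist)
        p_marg = np.einsum("k,tkY->tY", pk, p_cond)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p_cond > 0, np.log(
                np.maximum(p_cond, 1e-300) / np.maximum(p_marg[:, None, :],
                                                        1e-300)), 0.0)
        mi = np.einsum("k,tkY,tkY->t", pk, p_cond, ratio)
        return np.maximum(mi, 0.0)

    raw_nats = mi_curve(cond_onehot)
    null = np.empty((n_shuffles, T))
    for s in range(n_shuffles):
        perm = rng.permutation(n_tr)
        onehot = np.zeros_like(cond_onehot)
        onehot[cond_idx[perm], np.arange(n_tr)] = 1.0
        null[s] = mi_curve(onehot)

    conv = 1.0 / np.log(2.0) if base == "bits" else 1.0
    raw = raw_nats * conv
    null *= conv
    null_mean = null.mean(axis=0)
    ci95 = np.percentile(null, 95, axis=0)

    return MetricSeries(
        name="mi", group=group, time=design.time(), values=raw - null_mean,
        raw=raw, null_mean=null_mean, null_ci95=ci95,
        significant=raw > ci95, n_shuffles=n_shuffles,
        alignment="t_start",
        extras={"H_x": H_x * conv, "base": base, "n_trials": n_tr})


def dprime(
    spikes: SpikeData,
    session: Session,
    n_shuffles: int = 1000,
    seed: int = 0,
    smooth_bins: int = 5,
    conditions: Tuple[str, str] = ("win", "loss"),
) -> MetricSeries:
    """Shuffle-corrected unsigned d' between previous-win and previous-loss.

    Per time bin: |mean difference| over the pooled SD of the two
    condition distributions of smoothed single-trial rates.  The shuffle
    null rebuilds both pseudo-conditions from balanced draws of the
    pooled trials; the reported value subtracts the shuffle mean and the
    significance mask marks bins above the one-sided 95th percentile.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]).spawn(1)[0])
    prev = np.array([tr.prev_outcome for tr in session.trials])
    idx_a = np.nonzero(prev == conditions[0])[0]
    idx_b = np.nonzero(prev == conditions[1])[0]
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both previous-outcome conditions must be populated")

    rates = smooth_boxcar(spikes.binned_counts / spikes.dt, width=smooth_bins,
                          axis=-1)

    def d_curve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        mu_a, mu_b = rates[a].mean(axis=0), rates[b].mean(axis=0)
        var = 0.5 * (rates[a].var(axis=0, ddof=1) +
                     rates[b].var(axis=0, ddof=1))
        sd = np.sqrt(var)
        if np.all(sd == 0):
            raise ValueError("zero pooled variance in both conditions")
        return np.abs(mu_a - mu_b) / np.where(sd > 0, sd, np.inf)

    raw = d_curve(idx_a, idx_b)

    # label permutation preserving the per-condition trial counts, so the
    # null is matched (balanced) to the data's trial-type composition
    n_a = len(idx_a)
    pool = np.concatenate([idx_a, idx_b])
    null = np.empty((n_shuffles, rates.shape[1]))
    for s in range(n_shuffles):
        perm = rng.permutation(pool)
        null[s] = d_curve(perm[:n_a], perm[n_a:])

    null_mean = null.mean(axis=0)
    ci95 = np.percentile(null, 95, axis=0)
    time = 0.5 * (spikes.bin_edges[:-1] + spikes.bin_edges[1:])

    return MetricSeries(
        name="dprime", group="rewardHistory", time=time,
        values=raw - null_mean, raw=raw, null_mean=null_mean, null_ci95=ci95,
        significant=raw > ci95, n_shuffles=n_shuffles, alignment="t_start",
        extras={"n_a": len(idx_a), "n_b": len(idx_b)})


def cluster_average(
    metrics: Sequence[MetricSeries],
    labels: np.ndarray,
    zero_nonsignificant: bool = True,
    drop_outliers: bool = True,
) -> Dict[int, Tuple[np.ndarray, np.ndarray]]:
    """Mean ± SEM of a metric over neurons in each cluster.

    For CPD-style series, non-significant bins are zeroed before
    averaging and flagged outlier units are dropped.  Singleton clusters
    get SEM = NaN.
    """
    labels = np.asarray(labels)
    if len(labels) != len(metrics):
        raise ValueError("labels must cover the metric neurons")
    out: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(labels):
        rows = []
        for m, lab in zip(metrics, labels):
            if lab != c:
                continue
            if drop_outliers and m.outlier:
                continue
            v = m.values.copy()
            if zero_nonsignificant:
                v[~m.significant] = 0.0
            rows.append(v)
        if not rows:
            raise ValueError(f"cluster {c} has no usable neurons")
        arr = np.vstack(rows)
        mean = arr.mean(axis=0)
        sem = (arr.std(axis=0, ddof=1) / np.sqrt(len(rows))
               if len(rows) > 1 else np.full(arr.shape[1], np.nan))
        out[int(c)] = (mean, sem)
    return out
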
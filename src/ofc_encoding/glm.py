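"""L2-penalized Poisson encoding GLM: fitting, cross-validation, comparison.

The model for spike counts y_t in 50 ms bins is
``y_t ~ Poisson(exp(X_t theta + theta_0))`` with an L2 penalty
``xi/2 ||theta||^2`` on the kernel weights (not the offset).  The
objective is convex; fits use L-BFGS with analytic gradients, and the
kernel covariance is the inverse Hessian at the optimum.
Hyperparameter xi is chosen by the balanced 5-partition scheme: four
partitions support 4-fold cross-validation, the fifth is held out for
xi selection and final R2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .design import DesignMatrix
from .task import Session, SpikeData

__all__ = [
    "GLMFit", "CVScheme",
    "fit_glm", "partition_trials", "select_model",
    "predict_rate", "poisson_nll", "r2_heldout",
    "compare_variants", "smooth_boxcar",
]

_ETA_MAX = 30.0  # log-rate guard inside the optimizer only


@dataclass
class GLMFit:
    """Fitted model: kernel weights per variable plus background rate."""

    theta: np.ndarray = field(repr=False)        # (n_vars*M + 1,), offset last
    variables: Tuple[str, ...]
    n_basis: int
    xi: float
    nll_train: float
    converged: bool
    nll_val: Optional[float] = None
    nll_test: Optional[float] = None
    r2_test: Optional[float] = None
    kernel_cov: Optional[np.ndarray] = field(default=None, repr=False)
    search_history: Optional[list] = field(default=None, repr=False)

    @property
    def theta0(self) -> float:
        return float(self.theta[-1])

    def weights(self, variable: str) -> np.ndarray:
        j = self.variables.index(variable)
        M = self.n_basis
        return self.theta[j * M:(j + 1) * M]

    def kernels(self, basis) -> Dict[str, np.ndarray]:
        """Reconstruct temporal kernels k_s(tau) = sum_j theta_s^(j) phi_j."""
        return {v: basis.kernel(self.weights(v)) for v in self.variables}


@dataclass
class CVScheme:
    """Trial partition labels (1..n_parts) balanced over trial contingencies."""

    labels: np.ndarray
    test_partition: int
    balance_report: pd.DataFrame
    n_parts: int = 5

    def trials_in(self, parts: Sequence[int]) -> np.ndarray:
        return np.nonzero(np.isin(self.labels, list(parts)))[0]


def _objective(theta: np.ndarray, X: np.ndarray, y: np.ndarray, xi: float):
    eta = X @ theta[:-1] + theta[-1]
    eta_c = np.minimum(eta, _ETA_MAX)
    lam = np.exp(eta_c)
    f = float(np.sum(lam - y * eta)) + 0.5 * xi * float(theta[:-1] @ theta[:-1])
    resid = lam - y
    g = np.empty_like(theta)
    g[:-1] = X.T @ resid + xi * theta[:-1]
    g[-1] = resid.sum()
    return f, g


def _newton_polish(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                   xi: float, gtol: float, max_iter: int = 50):
    """Damped Newton refinement to gradient tolerance (convex objective).

    The tolerance is applied to the gradient infinity-norm scaled by the
    number of observations, so it is invariant to dataset size.
    """
    n = X.shape[0]
    f, g = _objective(theta, X, y, xi)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < gtol * n:
            return theta, True
        lam = predict_rate(theta, X)
        Xw = X * lam[:, None]
        p = len(theta)
        H = np.empty((p, p))
        H[:-1, :-1] = X.T @ Xw + xi * np.eye(p - 1)
        H[:-1, -1] = Xw.sum(axis=0)
        H[-1, :-1] = H[:-1, -1]
        H[-1, -1] = lam.sum()
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(30):
            f_new, g_new = _objective(theta - t * step, X, y, xi)
            if f_new <= f - 1e-4 * t * float(g @ step):
                theta, f, g = theta - t * step, f_new, g_new
                break
            t *= 0.5
        else:
            break
    return theta, bool(np.max(np.abs(g)) < gtol * n)


def poisson_nll(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Unpenalized Poisson negative log-likelihood (nats, up to log y! const)."""
    eta = X @ theta[:-1] + theta[-1]
    return float(np.sum(np.exp(np.minimum(eta, _ETA_MAX)) - y * eta))


def predict_rate(theta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Predicted mean counts per bin."""
    return np.exp(np.minimum(X @ theta[:-1] + theta[-1], _ETA_MAX))


def fit_glm(
    counts: np.ndarray,
    design: DesignMatrix,
    xi: float,
    theta_init: Optional[np.ndarray] = None,
    trial_idx: Optional[np.ndarray] = None,
    compute_cov: bool = False,
    gtol: float = 1e-6,
) -> GLMFit:
    """Minimize the penalized Poisson NLL for one neuron.

    ``counts`` may be (n_trials, n_bins) or flat; ``trial_idx`` restricts
    fitting to a subset of trials.  With ``compute_cov`` the block kernel
    covariance is estimated as the inverse Hessian at the optimum.
    """
    if xi < 0:
        raise ValueError("xi must be non-negative")
    y = np.asarray(counts, dtype=float)
    if y.ndim == 2:
        y = y.reshape(-1)
    X = design.X
    if trial_idx is not None:
        rows = design.rows_for_trials(np.asarray(trial_idx))
        X, y = X[rows], y.reshape(-1)[rows]
    if X.shape[0] != y.shape[0]:
        raise ValueError("design rows do not align with count bins")

    n_par = X.shape[1] + 1
    if theta_init is None:
        theta_init = np.zeros(n_par)
        theta_init[-1] = np.log(max(y.mean(), 1e-3))

    res = scipy.optimize.minimize(
        _objective, theta_init, args=(X, y, xi), jac=True, method="L-BFGS-B",
        options={"maxiter": 300, "gtol": 1e-5, "ftol": 1e-12})
    theta, converged = _newton_polish(res.x, X, y, xi, gtol)
    if not converged:
        warnings.warn("GLM fit did not converge to gradient tolerance")

    cov = None
    if compute_cov:
        lam = predict_rate(theta, X)
        H = np.zeros((n_par, n_par))
        Xw = X * lam[:, None]
        H[:-1, :-1] = X.T @ Xw + xi * np.eye(n_par - 1)
        H[:-1, -1] = Xw.sum(axis=0)
        H[-1, :-1] = H[:-1, -1]
        H[-1, -1] = lam.sum()
        cov = np.linalg.pinv(H)
        cov = 0.5 * (cov + cov.T)

    return GLMFit(theta=theta, variables=design.variables,
                  n_basis=design.basis.n_basis, xi=xi,
                  nll_train=poisson_nll(theta, X, y),
                  converged=converged, kernel_cov=cov)


# ---------------------------------------------------------------------------
# Cross-validation

def partition_trials(session: Session, seed: int = 0, n_parts: int = 5) -> CVScheme:
    """Greedy stratified split on the joint (outcome, prev-outcome, choice) cell.

    Trials within each joint cell are shuffled deterministically and dealt
    round-robin to partitions, so each condition's count differs by at most
    one across partitions wherever feasible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]).spawn(1)[0])
    n = session.n_trials
    if n < n_parts:
        raise ValueError("fewer trials than partitions")
    keys = [(tr.outcome, tr.prev_outcome, tr.choice) for tr in session.trials]
    labels = np.zeros(n, dtype=int)
    # greedy assignment: each trial goes to the partition with the lowest
    # combined load on its joint cell, its three marginals, and its total
    totals = np.zeros(n_parts)
    cell_counts: Dict[tuple, np.ndarray] = {}
    marg_counts: Dict[tuple, np.ndarray] = {}
    for cell in sorted(set(keys)):
        idx = np.array([i for i, k in enumerate(keys) if k == cell])
        rng.shuffle(idx)
        for i in idx:
            o, pr, ch = keys[i]
            cost = totals.copy()
            cost += 10.0 * cell_counts.setdefault(cell, np.zeros(n_parts))
            for dim, val in (("outcome", o), ("prev", pr), ("choice", ch)):
                cost += 3.0 * marg_counts.setdefault((dim, val),
                                                    np.zeros(n_parts))
            p = int(np.argmin(cost))
            labels[i] = p + 1
            totals[p] += 1
            cell_counts[cell][p] += 1
            for dim, val in (("outcome", o), ("prev", pr), ("choice", ch)):
                marg_counts[(dim, val)][p] += 1

    rows = []
    for p in range(1, n_parts + 1):
        sel = [session.trials[i] for i in np.nonzero(labels == p)[0]]
        rows.append({
            "partition": p, "n": len(sel),
            "win": sum(t.outcome == "win" for t in sel),
            "loss": sum(t.outcome == "loss" for t in sel),
            "prevWin": sum(t.prev_outcome == "win" for t in sel),
            "prevLoss": sum(t.prev_outcome == "loss" for t in sel),
            "left": sum(t.choice == "left" for t in sel),
            "right": sum(t.choice == "right" for t in sel),
        })
    report = pd.DataFrame(rows).set_index("partition")
    return CVScheme(labels=labels, test_partition=n_parts,
                    balance_report=report, n_parts=n_parts)


def _xi_grid(lo: float, hi: float, n: int) -> np.ndarray:
    return np.geomspace(lo, hi, n)


def select_model(
    counts: np.ndarray,
    design: DesignMatrix,
    scheme: CVScheme,
    xi_range: Tuple[float, float] = (1e-5, 10.0),
    n_grid: int = 7,
    n_rounds: int = 3,
    compute_cov: bool = True,
) -> GLMFit:
    """Nested search for xi on an iteratively refined log-spaced grid.

    For each candidate xi, four models are fit by 4-fold cross-validation
    on the non-test partitions and the fold model with lowest validation
    NLL is kept; the xi minimizing NLL on the held-out test partition wins.
    The returned fit carries nll_val/nll_test/r2_test and the kernel
    covariance of the winning model.
    """
    y = np.asarray(counts, dtype=float).reshape(design.n_trials, design.n_bins)
    test_trials = scheme.trials_in([scheme.test_partition])
    train_parts = [p for p in range(1, scheme.n_parts + 1)
                   if p != scheme.test_partition]
    rows_test = design.rows_for_trials(test_trials)
    X_test, y_test = design.X[rows_test], y.reshape(-1)[rows_test]

    evaluated: Dict[float, Tuple[float, GLMFit]] = {}
    warm: Optional[np.ndarray] = None

    def evaluate(xi: float) -> float:
        if xi in evaluated:
            return evaluated[xi][0]
        nonlocal warm
        best_fold: Optional[GLMFit] = None
        for val_part in train_parts:
            fit_trials = scheme.trials_in([p for p in train_parts
                                           if p != val_part])
            val_trials = scheme.trials_in([val_part])
            fit = fit_glm(y, design, xi, theta_init=warm, trial_idx=fit_trials)
            rows_val = design.rows_for_trials(val_trials)
            fit.nll_val = poisson_nll(fit.theta, design.X[rows_val],
                                      y.reshape(-1)[rows_val])
            if best_fold is None or fit.nll_val < best_fold.nll_val:
                best_fold = fit
            warm = fit.theta.copy()
        best_fold.nll_test = poisson_nll(best_fold.theta, X_test, y_test)
        evaluated[xi] = (best_fold.nll_test, best_fold)
        return best_fold.nll_test

    lo, hi = xi_range
    grid = _xi_grid(lo, hi, n_grid)
    for _ in range(n_rounds):
        scores = [evaluate(x) for x in grid]
        j = int(np.argmin(scores))
        lo_j, hi_j = max(0, j - 1), min(len(grid) - 1, j + 1)
        grid = _xi_grid(grid[lo_j], grid[hi_j], n_grid)

    if not any(f.converged for _, f in evaluated.values()):
        raise RuntimeError("all GLM fits diverged during model selection")

    xi_best = min(evaluated, key=lambda x: evaluated[x][0])
    best = evaluated[xi_best][1]
    best.search_history = sorted((x, nll) for x, (nll, _) in evaluated.items())
    best.r2_test = r2_heldout(best, y, design, test_trials)
    if compute_cov:
        fit_trials = scheme.trials_in(train_parts)
        refit = fit_glm(y, design, xi_best, theta_init=best.theta,
                        trial_idx=fit_trials, compute_cov=True)
        best.kernel_cov = refit.kernel_cov
    return best


# ---------------------------------------------------------------------------
# Goodness of fit and model comparison

def smooth_boxcar(x: np.ndarray, width: int = 5, axis: int = -1) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges
    (matches MATLAB ``smooth`` with a 250 ms / 5-bin span on 50 ms bins)."""
    x = np.asarray(x, dtype=float)
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    half = width // 2
    out = np.empty_like(x)
    csum = np.cumsum(np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        w = min(i - lo, hi - 1 - i)  # symmetric shrink at edges
        lo, hi = i - w, i + w + 1
        out[..., i] = (csum[..., hi] - csum[..., lo]) / (hi - lo)
    return np.moveaxis(out, -1, axis)


def r2_heldout(
    fit: GLMFit,
    counts: np.ndarray,
    design: DesignMatrix,
    test_trials: np.ndarray,
) -> float:
    """Variance explained on held-out trials.

    Both observed counts and predicted rates are converted to Hz and
    smoothed with the 250 ms moving average before computing
    ``1 - SSE(model)/SSE(mean)``; may be negative.
    """
    y = np.asarray(counts, dtype=float).reshape(design.n_trials, design.n_bins)
    rows = design.rows_for_trials(test_trials)
    dt = design.basis.dt
    obs = smooth_boxcar(y[test_trials] / dt, axis=-1)
    pred = predict_rate(fit.theta, design.X[rows]).reshape(len(test_trials), -1) / dt
    pred = smooth_boxcar(pred, axis=-1)
    denom = float(np.sum((obs - obs.mean()) ** 2))
    if denom == 0:
        raise ValueError("zero-variance held-out data")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / denom


def kernel_recovery(neuron, fit: GLMFit, basis,
                    min_peak: float = 0.3) -> Dict[str, float]:
    """Correlations between planted and recovered kernels.

    The left/right and safe/risky choice streams share the center-exit
    anchor and are exactly collinear, so only their per-condition sums are
    identifiable; those effective kernels are compared for the four
    observable (side, safety) combinations.  Kernels whose planted peak
    modulation is below ``min_peak`` log-units (< ~35% rate modulation)
    are skipped: at a few hundred trials their estimates sit at the noise
    floor, so correlation there measures noise rather than recovery.
    """
    choice_vars = {"leftChoice", "rightChoice", "safeChoice", "riskyChoice"}

    def planted(v: str) -> np.ndarray:
        w = neuron.kernel_weights.get(v)
        return basis.kernel(w) if w is not None else np.zeros(basis.n_lags)

    out: Dict[str, float] = {}
    for v in neuron.kernel_weights:
        if v in choice_vars:
            continue
        k_true = planted(v)
        if np.max(np.abs(k_true)) < min_peak:
            continue
        out[v] = float(np.corrcoef(k_true, basis.kernel(fit.weights(v)))[0, 1])
    for side in ("left", "right"):
        for safety in ("safe", "risky"):
            k_true = planted(f"{side}Choice") + planted(f"{safety}Choice")
            if np.max(np.abs(k_true)) < min_peak:
                continue
            k_fit = (basis.kernel(fit.weights(f"{side}Choice")) +
                     basis.kernel(fit.weights(f"{safety}Choice")))
            out[f"{side}+{safety}"] = float(np.corrcoef(k_true, k_fit)[0, 1])
    return out


def compare_variants(nll_table: pd.DataFrame) -> pd.DataFrame:
    """Population-level model comparison via Wilcoxon signed-rank tests.

    ``nll_table`` holds per-neuron held-out NLLs, one column per model
    variant.  Returns one row per ordered column pair with the two-sided
    p-value and the median paired difference (A - B).
    """
    if len(nll_table) < 6:
        raise ValueError("need at least 6 paired NLLs for a signed-rank test")
    out = []
    cols = list(nll_table.columns)
    for a in cols:
        for b in cols:
            if a == b:
                continue
            d = nll_table[a].to_numpy() - nll_table[b].to_numpy()
            if np.allclose(d, 0):
                p = 1.0
            else:
                p = float(scipy.stats.wilcoxon(d).pvalue)
            out.append({"variant_a": a, "variant_b": b,
                        "median_diff": float(np.median(d)), "p": p})
    return pd.DataFrame(out)
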
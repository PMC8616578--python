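"""Design matrices: task-variable impulse streams convolved with the basis.

The default encoding uses 15 time-dependent task variables, one-hot per
condition: four stimulus streams (left/right clicks and flashes, at their
own event times), left/right and safe/risky choice (at center-port exit),
win/loss (at side-port entry, which is reward delivery on wins), previous
win/loss/opt-out, previous reward rate and session progress (all at trial
start; the last two as scalar-amplitude impulses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.signal import fftconvolve

from .basis import BasisSet, build_basis
from .task import Session, Trial

__all__ = [
    "TASK_VARIABLES",
    "DESIGN_VARIANTS",
    "DesignMatrix",
    "build_design_matrix",
]

#: the 15 task variables of the default model, in design order
TASK_VARIABLES = (
    "leftClick", "rightClick", "leftFlash", "rightFlash",
    "leftChoice", "rightChoice", "safeChoice", "riskyChoice",
    "win", "loss",
    "prevWin", "prevLoss", "prevOptOut",
    "prevRewardRate", "sessionProgress",
)

DESIGN_VARIANTS = (
    "default",
    "plus_volume",          # + currentVolume, previousVolume (scalar, µl)
    "minus_extras",         # - prevOptOut, prevRewardRate, sessionProgress
    "minus_reward_history", # - prevWin, prevLoss, prevOptOut
    "symmetric",            # ±1 coding collapses each condition pair
)


@dataclass
class DesignMatrix:
    """Basis-convolved regressors on the concatenated per-trial 50 ms grid."""

    variables: Tuple[str, ...]
    streams: np.ndarray = field(repr=False)   # (n_trials, n_bins, n_vars)
    X: np.ndarray = field(repr=False)         # (n_trials * n_bins, n_vars * M)
    basis: BasisSet = field(repr=False)
    window: Tuple[float, float]
    variant: str = "default"

    @property
    def n_trials(self) -> int:
        return self.streams.shape[0]

    @property
    def n_bins(self) -> int:
        return self.streams.shape[1]

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def var_slice(self, name: str) -> slice:
        """Column slice of X belonging to one task variable."""
        j = self.variables.index(name)
        M = self.basis.n_basis
        return slice(j * M, (j + 1) * M)

    def rows_for_trials(self, trial_idx: np.ndarray) -> np.ndarray:
        """Row indices of X for a set of trials."""
        T = self.n_bins
        return (np.asarray(trial_idx)[:, None] * T + np.arange(T)[None, :]).ravel()

    def time(self) -> np.ndarray:
        """Bin centers in seconds relative to trial start."""
        return self.window[0] + (np.arange(self.n_bins) + 0.5) * self.basis.dt


def _bin_of(t_rel: np.ndarray, window: Tuple[float, float], dt: float,
            n_bins: int) -> np.ndarray:
    b = np.floor((np.asarray(t_rel, dtype=float) - window[0]) / dt).astype(int)
    return b[(b >= 0) & (b < n_bins)]


def _trial_streams(tr: Trial, variables: Tuple[str, ...],
                   window: Tuple[float, float], dt: float,
                   n_bins: int) -> np.ndarray:
    S = np.zeros((n_bins, len(variables)))

    def put(name: str, times, amplitude: float = 1.0, binarize: bool = True):
        if name not in variables:
            return
        j = variables.index(name)
        bins = _bin_of(np.atleast_1d(times) - tr.t_start, window, dt, n_bins)
        if binarize:
            S[bins, j] = amplitude
        else:
            np.add.at(S[:, j], bins, amplitude)

    put("leftClick", tr.click_times_L)
    put("rightClick", tr.click_times_R)
    put("leftFlash", tr.flash_times_L)
    put("rightFlash", tr.flash_times_R)

    put("leftChoice" if tr.choice == "left" else "rightChoice", tr.t_exit_center)
    put("safeChoice" if tr.chose_safe == "safe" else "riskyChoice",
        tr.t_exit_center)

    if tr.outcome in ("win", "loss"):
        put(tr.outcome, tr.t_choice)
        put("currentVolume", tr.t_choice, amplitude=tr.V_rewarded)

    if tr.prev_outcome != "none":
        put({"win": "prevWin", "loss": "prevLoss",
             "opt_out": "prevOptOut"}[tr.prev_outcome], tr.t_start)
    put("prevRewardRate", tr.t_start, amplitude=tr.prev_reward_rate)
    put("sessionProgress", tr.t_start, amplitude=tr.session_progress)

    # symmetric (±1) variant streams
    if "outcome_sym" in variables and tr.outcome in ("win", "loss"):
        put("outcome_sym", tr.t_choice,
            amplitude=1.0 if tr.outcome == "win" else -1.0)
    if "choice_sym" in variables:
        put("choice_sym", tr.t_exit_center,
            amplitude=1.0 if tr.choice == "left" else -1.0)
    if "safety_sym" in variables:
        put("safety_sym", tr.t_exit_center,
            amplitude=1.0 if tr.chose_safe == "safe" else -1.0)
    if "prevOutcome_sym" in variables and tr.prev_outcome in ("win", "loss"):
        put("prevOutcome_sym", tr.t_start,
            amplitude=1.0 if tr.prev_outcome == "win" else -1.0)
    return S


def _variant_variables(variant: str) -> Tuple[str, ...]:
    base = list(TASK_VARIABLES)
    if variant == "default":
        return tuple(base)
    if variant == "plus_volume":
        return tuple(base + ["currentVolume", "previousVolume"])
    if variant == "minus_extras":
        drop = {"prevOptOut", "prevRewardRate", "sessionProgress"}
        return tuple(v for v in base if v not in drop)
    if variant == "minus_reward_history":
        drop = {"prevWin", "prevLoss", "prevOptOut"}
        return tuple(v for v in base if v not in drop)
    if variant == "symmetric":
        keep = ["leftClick", "rightClick", "leftFlash", "rightFlash",
                "prevOptOut", "prevRewardRate", "sessionProgress"]
        return tuple(keep + ["choice_sym", "safety_sym", "outcome_sym",
                             "prevOutcome_sym"])
    raise ValueError(f"unknown design variant: {variant!r}")


def build_design_matrix(
    session: Session,
    basis: Optional[BasisSet] = None,
    variant: str = "default",
    window: Tuple[float, float] = (-2.0, 6.0),
) -> DesignMatrix:
    """Build impulse streams and their causal basis convolution.

    Each trial contributes an independent window (default [-2, 6] s around
    trial start) of 50 ms bins; convolution with the kernel basis is causal
    in lag with the basis' 4 s support and does not cross trial windows.
    ``previousVolume`` in the ``plus_volume`` variant is the rewarded volume
    of the immediately preceding trial.
    """
    if basis is None:
        basis = build_basis()
    variables = _variant_variables(variant)
    dt = basis.dt
    n_bins = int(round((window[1] - window[0]) / dt))

    streams = np.zeros((session.n_trials, n_bins, len(variables)))
    for i, tr in enumerate(session.trials):
        streams[i] = _trial_streams(tr, variables, window, dt, n_bins)

    if "previousVolume" in variables:
        j = variables.index("previousVolume")
        b0 = _bin_of(np.array([0.0]), window, dt, n_bins)
        for i, tr in enumerate(session.trials):
            if i > 0:
                streams[i, b0, j] = session.trials[i - 1].V_rewarded

    # causal convolution, trial by trial, all variables/basis at once
    conv = fftconvolve(streams[:, :, :, None], basis.B[None, :, None, :],
                       axes=1)[:, :n_bins]
    n_trials = session.n_trials
    X = conv.reshape(n_trials, n_bins, len(variables) * basis.n_basis)
    X = np.ascontiguousarray(X.reshape(n_trials * n_bins, -1))
    # fftconvolve leaves tiny negative residues on exact zeros
    X[np.abs(X) < 1e-12] = 0.0

    return DesignMatrix(variables=variables, streams=streams, X=X,
                        basis=basis, window=window, variant=variant)
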
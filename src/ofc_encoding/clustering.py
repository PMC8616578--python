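"""Response clustering: PSTH and conditional feature spaces, k-means.

Two complementary featurizations of a population of units:

* trial-averaged, z-scored PSTHs aligned to trial start ([-2, 4] s at
  50 ms, 121 bins), reduced by PCA to >95% variance;
* a 19-dimensional conditional feature space — epoch-averaged z-scored
  rates conditioned on outcome, rewarded volume, previous outcome,
  choice side, and binned left/right expected value — likewise reduced
  by PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .glm import smooth_boxcar
from .task import Session, SpikeData, Trial

__all__ = [
    "PSTHMatrix", "FeatureSpace", "ClusterResult",
    "compute_psth", "psth_matrix",
    "build_psth_feature_space", "build_conditional_feature_space",
    "conditional_features",
    "kmeans_cluster", "cluster_consistency",
    "CONDITIONAL_FEATURE_NAMES",
]

logger = logging.getLogger(__name__)

#: ordering of the 19 conditional features
CONDITIONAL_FEATURE_NAMES = (
    "outcome:win", "outcome:loss",
    "rewVol:0", "rewVol:6", "rewVol:12", "rewVol:24", "rewVol:48",
    "prev:win", "prev:loss",
    "choice:left", "choice:right",
    "EVL:[0,6)", "EVL:[6,12)", "EVL:[12,24)", "EVL:[24,48]",
    "EVR:[0,6)", "EVR:[6,12)", "EVR:[12,24)", "EVR:[24,48]",
)

_EV_EDGES = (0.0, 6.0, 12.0, 24.0, 48.0 + 1e-9)


@dataclass
class PSTHMatrix:
    """Z-scored trial-averaged PSTHs, one row per neuron."""

    Z: np.ndarray = field(repr=False)      # (n_neurons, n_bins)
    time: np.ndarray = field(repr=False)   # bin centers, s relative to event
    alignment: str = "t_start"
    smoothing_s: float = 0.25
    kept: np.ndarray = field(default=None, repr=False)  # rows retained


@dataclass
class FeatureSpace:
    """PCA scores retaining >95% cumulative variance."""

    M_scores: np.ndarray = field(repr=False)
    W_loadings: np.ndarray = field(repr=False)
    var_explained: np.ndarray
    mean_: np.ndarray = field(repr=False)
    source: str = "psth"
    raw: np.ndarray = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.M_scores.shape[1]


@dataclass
class ClusterResult:
    labels: np.ndarray
    centroids: np.ndarray = field(repr=False)
    K: int = 0
    inertia: float = 0.0
    seed: int = 0
    replicates: int = 50


def _bin_spikes(spikes: SpikeData, session: Session, align: str,
                window: Tuple[float, float], dt: float = 0.05,
                trials: Optional[np.ndarray] = None) -> np.ndarray:
    """Counts (n_sel_trials, n_bins) re-aligned to a per-trial event.

    The grid has bin centers at window[0] .. window[1] inclusive (so the
    default [-2, 4] s trial-start window has 121 bins).
    """
    n_bins = int(round((window[1] - window[0]) / dt)) + 1
    edges = window[0] - dt / 2 + np.arange(n_bins + 1) * dt
    if trials is None:
        trials = np.arange(session.n_trials)
    out = np.zeros((len(trials), n_bins))
    for r, i in enumerate(trials):
        tr = session.trials[i]
        offset = getattr(tr, align) - tr.t_start if align != "t_start" else 0.0
        t_rel = spikes.spike_times[i] - offset
        out[r], _ = np.histogram(t_rel, bins=edges)
    return out


def compute_psth(
    spikes: SpikeData,
    session: Session,
    align: str = "t_start",
    window: Tuple[float, float] = (-2.0, 4.0),
    condition_filter: Optional[Callable[[Trial], bool]] = None,
    dt: float = 0.05,
    smooth_bins: int = 5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Trial-averaged smoothed firing rate (Hz) aligned to a task event.

    Returns ``(time, rate)``; time gives bin centers relative to the
    alignment event.  ``condition_filter`` restricts the trial set.
    """
    if condition_filter is None:
        trials = np.arange(session.n_trials)
    else:
        trials = np.array([i for i, tr in enumerate(session.trials)
                           if condition_filter(tr)])
    if len(trials) == 0:
        raise ValueError("no trials satisfy the condition filter")
    counts = _bin_spikes(spikes, session, align, window, dt, trials)
    rate = smooth_boxcar(counts.mean(axis=0) / dt, width=smooth_bins)
    n_bins = counts.shape[1]
    time = window[0] + np.arange(n_bins) * dt
    return time, rate


def psth_matrix(
    spike_list: Sequence[SpikeData],
    session: Session,
    align: str = "t_start",
    window: Tuple[float, float] = (-2.0, 4.0),
) -> PSTHMatrix:
    """Stack z-scored trial-averaged PSTHs into a neurons x bins matrix.

    Rows with zero variance (silent units) are dropped with a warning;
    ``kept`` records the surviving row indices.
    """
    rows, kept = [], []
    time = None
    for i, sp in enumerate(spike_list):
        time, rate = compute_psth(sp, session, align=align, window=window)
        sd = rate.std()
        if sd == 0:
            logger.warning("dropping constant-rate unit %s from PSTH matrix",
                           sp.unit_id)
            continue
        rows.append((rate - rate.mean()) / sd)
        kept.append(i)
    Z = np.vstack(rows)
    return PSTHMatrix(Z=Z, time=time, alignment=align,
                      kept=np.array(kept, dtype=int))


def _pca_95(Z: np.ndarray, source: str, threshold: float = 0.95) -> FeatureSpace:
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 neurons for PCA")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, threshold) + 1)
    k = min(k, scores.shape[1])
    return FeatureSpace(M_scores=scores[:, :k],
                        W_loadings=pca.components_[:k],
                        var_explained=pca.explained_variance_ratio_[:k],
                        mean_=pca.mean_, source=source, raw=Z)


def build_psth_feature_space(psths: PSTHMatrix | np.ndarray,
                             threshold: float = 0.95) -> FeatureSpace:
    """PCA of the z-scored PSTH matrix, retaining >95% variance."""
    Z = psths.Z if isinstance(psths, PSTHMatrix) else np.asarray(psths, float)
    return _pca_95(Z, "psth", threshold)


def _epoch_mean(spikes: SpikeData, session: Session, align: str,
                window: Tuple[float, float], trials: np.ndarray) -> float:
    counts = _bin_spikes(spikes, session, align, window, trials=trials)
    dt = 0.05
    return float(counts.mean() / dt)


def conditional_features(spikes: SpikeData, session: Session) -> np.ndarray:
    """The 19 conditional features for one neuron (z-scored epoch means).

    Conditional rates are z-scored with the neuron's marginal (pooled)
    statistics so conditions remain comparable; empty condition cells are
    imputed with the neuron's marginal mean for that epoch and logged.
    Opt-out trials enter only through the outcome=0-volume exclusion
    rules (they are excluded everywhere except as previous-trial history
    carriers).
    """
    trials = session.trials
    non_opt = np.array([i for i, t in enumerate(trials) if t.outcome != "opt_out"])

    # marginal stats from the trial-start window across all trials
    all_counts = _bin_spikes(spikes, session, "t_start", (-2.0, 4.0),
                             trials=np.arange(session.n_trials))
    rates = all_counts / 0.05
    mu, sd = float(rates.mean()), float(rates.std())
    if sd == 0:
        sd = 1.0

    def z_epoch(align: str, window: Tuple[float, float],
                idx: np.ndarray, name: str) -> float:
        if len(idx) == 0:
            logger.warning("empty condition cell %r; imputing marginal mean",
                           name)
            return np.nan
        return (_epoch_mean(spikes, session, align, window, idx) - mu) / sd

    feats = {}
    feats["outcome:win"] = z_epoch("t_choice", (0.0, 3.0), np.array(
        [i for i in non_opt if trials[i].outcome == "win"]), "outcome:win")
    feats["outcome:loss"] = z_epoch("t_choice", (0.0, 3.0), np.array(
        [i for i in non_opt if trials[i].outcome == "loss"]), "outcome:loss")
    for v in (0, 6, 12, 24, 48):
        idx = np.array([i for i in non_opt
                        if trials[i].V_rewarded == float(v)])
        feats[f"rewVol:{v}"] = z_epoch("t_choice", (0.0, 3.0), idx, f"rewVol:{v}")
    for prev in ("win", "loss"):
        idx = np.array([i for i, t in enumerate(trials)
                        if t.prev_outcome == prev])
        feats[f"prev:{prev}"] = z_epoch("t_start", (-1.0, 2.0), idx,
                                        f"prev:{prev}")
    for side in ("left", "right"):
        idx = np.array([i for i in non_opt if trials[i].choice == side])
        feats[f"choice:{side}"] = z_epoch("t_exit_center", (0.0, 1.5), idx,
                                          f"choice:{side}")
    for prefix, attr in (("EVL", "EV_left"), ("EVR", "EV_right")):
        for b in range(4):
            lo, hi = _EV_EDGES[b], _EV_EDGES[b + 1]
            idx = np.array([i for i in non_opt
                            if lo <= getattr(trials[i], attr) < hi])
            name = CONDITIONAL_FEATURE_NAMES[11 + (0 if prefix == "EVL" else 4) + b]
            feats[name] = z_epoch("t_choice", (-1.0, 0.0), idx, name)

    vec = np.array([feats[n] for n in CONDITIONAL_FEATURE_NAMES])
    if np.any(np.isnan(vec)):
        # impute empty cells with the neuron's marginal mean (0 in z-units)
        vec = np.where(np.isnan(vec), np.nanmean(vec), vec)
    return vec


def build_conditional_feature_space(
    spike_list: Sequence[SpikeData],
    session: Session,
    threshold: float = 0.95,
) -> FeatureSpace:
    """19 conditional features per neuron, then PCA to >95% variance."""
    F = np.vstack([conditional_features(sp, session) for sp in spike_list])
    return _pca_95(F, "conditional", threshold)


def kmeans_cluster(features: FeatureSpace | np.ndarray, K: int,
                   seed: int = 0, replicates: int = 50) -> ClusterResult:
    """Best of ``replicates`` k-means++ runs by inertia; seed-deterministic."""
    X = features.M_scores if isinstance(features, FeatureSpace) else np.asarray(features)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > X.shape[0]:
        raise ValueError("K exceeds number of neurons")
    km = KMeans(n_clusters=K, n_init=replicates, random_state=seed)
    labels = km.fit_predict(X) + 1
    return ClusterResult(labels=labels, centroids=km.cluster_centers_, K=K,
                         inertia=float(km.inertia_), seed=seed,
                         replicates=replicates)


def cluster_consistency(labels_a: np.ndarray, labels_b: np.ndarray) -> np.ndarray:
    """Conditional probability matrix P(C_b = j | C_a = i).

    Cluster correspondence is first resolved by maximal-overlap matching
    (Hungarian assignment on the contingency table), then rows are
    normalized to sum to 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings cover different neuron sets")
    ka = np.unique(a)
    kb = np.unique(b)
    C = np.zeros((len(ka), len(kb)))
    for i, ci in enumerate(ka):
        for j, cj in enumerate(kb):
            C[i, j] = np.sum((a == ci) & (b == cj))
    if len(ka) == len(kb):
        _, perm = linear_sum_assignment(-C)
        C = C[:, perm]
    row_sums = C.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    return C / row_sums
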
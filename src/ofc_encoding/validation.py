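"""Cluster-number selection and clusteredness statistics.

Implements the gap statistic with a PCA-aligned uniform reference, the
silhouette score and subsampled adjusted Rand index (via scikit-learn),
cluster-averaged Mahalanobis separation, the PAIRS nearest-neighbor-angle
statistic with its Gaussian reference, and the covariance-regime
experiment comparing silhouette- and gap-selected cluster numbers on
ground-truth data with controlled cluster packing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_score

__all__ = [
    "GapCurve", "PAIRSResult", "SeparationResult",
    "gap_statistic", "silhouette", "ari_subsample",
    "mahalanobis_separation", "pairs", "select_pairs_k",
    "regime_experiment",
]


@dataclass
class GapCurve:
    K_grid: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    log_w: np.ndarray
    n_reference: int
    selected_K: int


@dataclass
class PAIRSResult:
    k_neighbors: int
    theta_data: np.ndarray = field(repr=False)
    theta_ref: np.ndarray = field(repr=False)
    pairs: float = 0.0
    p_two_sided: float = 1.0
    ks_p: float = 1.0
    n_reference: int = 10000
    angle_convention: str = "signed"


@dataclass
class SeparationResult:
    D_M: np.ndarray
    cluster_ids: np.ndarray


def _kmeans_inertia(X: np.ndarray, K: int, rng: np.random.Generator,
                    n_init: int = 5) -> float:
    if K == 1:
        mu = X.mean(axis=0)
        return float(np.sum((X - mu) ** 2))
    km = KMeans(n_clusters=K, n_init=n_init,
                random_state=int(rng.integers(2**31 - 1)))
    km.fit(X)
    return float(km.inertia_)


def gap_statistic(
    features: np.ndarray,
    K_grid: Sequence[int] = tuple(range(1, 16)),
    n_ref: int = 5000,
    seed: int = 0,
    n_init: int = 5,
) -> GapCurve:
    """Gap statistic over ``K_grid`` with a uniform PCA-aligned box reference.

    ``Gap(K) = E*[log W_K] - log W_K`` with ``SE(K) = sd*sqrt(1 + 1/B)``;
    the selected K is the largest one in the grid with
    ``Gap(K) >= Gap(K-1) + 2 SE(K-1)`` (1 if no significant jump exists).
    """
    X = np.asarray(features, dtype=float)
    K_grid = np.asarray(sorted(K_grid))
    if K_grid[0] != 1 or np.any(np.diff(K_grid) != 1):
        raise ValueError("K_grid must be contiguous from 1")
    if n_ref < 100:
        warnings.warn("n_ref < 100: gap statistic SE will be noisy")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]).spawn(1)[0])

    mu = X.mean(axis=0)
    Xc = X - mu
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xp = Xc @ Vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)

    log_w = np.array([np.log(_kmeans_inertia(X, K, rng, n_init))
                      for K in K_grid])
    log_w_ref = np.empty((n_ref, len(K_grid)))
    for b in range(n_ref):
        R = rng.uniform(lo, hi, size=Xp.shape) @ Vt + mu
        log_w_ref[b] = [np.log(_kmeans_inertia(R, K, rng, n_init))
                        for K in K_grid]

    gap = log_w_ref.mean(axis=0) - log_w
    se = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_ref)

    selected = 1
    for i in range(1, len(K_grid)):
        if gap[i] >= gap[i - 1] + 2.0 * se[i - 1]:
            selected = int(K_grid[i])
    return GapCurve(K_grid=K_grid, gap=gap, se=se, log_w=log_w,
                    n_reference=n_ref, selected_K=selected)


def silhouette(features: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score with Euclidean distances."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(np.asarray(features), labels,
                                  metric="euclidean"))


def ari_subsample(
    features: np.ndarray,
    K: int,
    frac: float = 0.9,
    n_rep: int = 100,
    seed: int = 0,
    replicates: int = 10,
) -> np.ndarray:
    """ARI between full-data and 90%-subsample clusterings, per replicate."""
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    if K < 2:
        raise ValueError("K must be >= 2")
    X = np.asarray(features, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]).spawn(1)[0])
    full = KMeans(n_clusters=K, n_init=replicates,
                  random_state=int(rng.integers(2**31 - 1))).fit_predict(X)
    n_sub = max(K, int(round(frac * X.shape[0])))
    out = np.empty(n_rep)
    for r in range(n_rep):
        idx = rng.choice(X.shape[0], size=n_sub, replace=False)
        sub = KMeans(n_clusters=K, n_init=replicates,
                     random_state=int(rng.integers(2**31 - 1))
                     ).fit_predict(X[idx])
        out[r] = adjusted_rand_score(full[idx], sub)
    return out


def mahalanobis_separation(features: np.ndarray, labels: np.ndarray,
                           ridge: float = 1e-8) -> SeparationResult:
    """K x K matrix of cluster-averaged Mahalanobis distances.

    Entry (A, B) averages the distance of cluster-A points to the mean and
    covariance of cluster B (own-cluster entries included).  Near-singular
    covariances get a ridge; clusters smaller than dimension + 1 fall back
    to the pseudo-inverse with a warning.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    d = X.shape[1]
    stats = {}
    for c in ids:
        pts = X[labels == c]
        mu = pts.mean(axis=0)
        if pts.shape[0] < 2:
            warnings.warn(f"cluster {c} is a singleton; "
                          "falling back to unit covariance")
            stats[c] = (mu, np.eye(d))
            continue
        S = np.atleast_2d(np.cov(pts, rowvar=False)) + ridge * np.eye(d)
        if pts.shape[0] < d + 1:
            warnings.warn(f"cluster {c} smaller than dimension+1; "
                          "using pseudo-inverse covariance")
            Sinv = np.linalg.pinv(S)
        else:
            Sinv = np.linalg.inv(S)
        stats[c] = (mu, Sinv)

    D = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        pts = X[labels == a]
        for j, b in enumerate(ids):
            mu, Sinv = stats[b]
            diff = pts - mu
            D[i, j] = np.mean(np.sqrt(np.einsum("nd,de,ne->n", diff, Sinv, diff)))
    return SeparationResult(D_M=D, cluster_ids=ids)


# ---------------------------------------------------------------------------
# PAIRS

def _whiten(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False)
    vals, vecs = np.linalg.eigh(np.atleast_2d(cov))
    vals = np.maximum(vals, 1e-12)
    return Xc @ vecs @ np.diag(vals ** -0.5) @ vecs.T


def _mean_neighbor_angles(X: np.ndarray, k: int, folded: bool) -> np.ndarray:
    """Per-point mean angle to its k nearest-by-angle neighbors."""
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    U = X / np.maximum(norms, 1e-300)
    C = np.clip(U @ U.T, -1.0, 1.0)
    A = np.arccos(np.abs(C)) if folded else np.arccos(C)
    np.fill_diagonal(A, np.inf)
    part = np.partition(A, k - 1, axis=1)[:, :k]
    return part.mean(axis=1)


def pairs(
    features: np.ndarray,
    k_neighbors: int,
    n_ref: int = 10000,
    seed: int = 0,
    angle: str = "signed",
) -> PAIRSResult:
    """PAIRS statistic against a standard-Gaussian reference.

    Data are whitened to zero mean and unit covariance; each point's mean
    angle to its ``k_neighbors`` nearest-by-angle neighbors forms the data
    distribution.  ``n_ref`` reference datasets of matched size and
    dimension give the grand reference distribution;
    ``PAIRS = (med_ref - med_data) / med_ref``, with a two-sided p-value
    from a normal fit to the per-reference PAIRS values and a KS test
    between the angle distributions.

    ``angle`` selects the sign convention: ``"signed"`` (arccos of the
    cosine, [0, pi]; default) or ``"folded"`` (arccos of |cosine|,
    [0, pi/2]).
    """
    X = np.asarray(features, dtype=float)
    N, D = X.shape
    if k_neighbors >= N:
        raise ValueError("k_neighbors must be smaller than the number of points")
    folded = {"signed": False, "folded": True}[angle]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]).spawn(1)[0])

    theta_data = _mean_neighbor_angles(_whiten(X), k_neighbors, folded)
    ref_angles = np.empty((n_ref, N))
    for b in range(n_ref):
        # references receive the same whitening as the data
        R = _whiten(rng.standard_normal((N, D)))
        ref_angles[b] = _mean_neighbor_angles(R, k_neighbors, folded)

    med_ref = float(np.median(ref_angles))
    med_data = float(np.median(theta_data))
    stat = (med_ref - med_data) / med_ref
    ref_pairs = (med_ref - np.median(ref_angles, axis=1)) / med_ref
    mu, sd = ref_pairs.mean(), ref_pairs.std(ddof=1)
    if sd == 0:
        p = 1.0
    else:
        zval = (stat - mu) / sd
        p = float(2.0 * scipy.stats.norm.sf(abs(zval)))
    ks = scipy.stats.ks_2samp(theta_data, ref_angles.ravel())

    return PAIRSResult(k_neighbors=k_neighbors, theta_data=theta_data,
                       theta_ref=ref_angles.ravel(), pairs=float(stat),
                       p_two_sided=p, ks_p=float(ks.pvalue), n_reference=n_ref,
                       angle_convention=angle)


def select_pairs_k(
    N: int,
    D: int,
    seed: int = 0,
    n_draws: int = 50,
    k_max: int = 30,
    threshold: float = np.pi / 4,
    angle: str = "signed",
) -> int:
    """Smallest neighbor count whose Gaussian-reference median angle
    exceeds ``threshold`` (pi/4 by default).

    Pools per-point mean neighbor angles over ``n_draws`` reference
    datasets of N standard-Gaussian points in D dimensions; for each
    candidate k the pooled median of mean angles to the k nearest-by-angle
    neighbors is compared against the threshold.
    """
    folded = {"signed": False, "folded": True}[angle]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 19]).spawn(1)[0])
    k_max = min(k_max, N - 1)
    pooled = np.empty((n_draws, N, k_max))
    for b in range(n_draws):
        R = rng.standard_normal((N, D))
        U = R / np.linalg.norm(R, axis=1, keepdims=True)
        C = np.clip(U @ U.T, -1.0, 1.0)
        A = np.arccos(np.abs(C)) if folded else np.arccos(C)
        np.fill_diagonal(A, np.inf)
        A_sorted = np.sort(A, axis=1)[:, :k_max]
        pooled[b] = np.cumsum(A_sorted, axis=1) / np.arange(1, k_max + 1)
    medians = np.median(pooled.reshape(-1, k_max), axis=0)
    hits = np.nonzero(medians > threshold)[0]
    if len(hits) == 0:
        raise RuntimeError(
            f"reference median angle never exceeds {threshold:.3f} up to "
            f"k={k_max}")
    return int(hits[0] + 1)


# ---------------------------------------------------------------------------
# Covariance-regime experiment

def _pca_95_scores(X: np.ndarray, threshold: float = 0.95) -> np.ndarray:
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, threshold) + 1)
    return scores[:, :min(k, scores.shape[1])]


def regime_experiment(
    total_cov: np.ndarray,
    within_cov: np.ndarray,
    scales: Sequence[float] = (0.1, 0.5, 1.0, 2.0, 3.0, 5.0),
    n_rep: int = 100,
    n_clusters: int = 5,
    points_per_cluster: int = 100,
    K_grid: Sequence[int] = tuple(range(1, 11)),
    gap_n_ref: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Silhouette- vs gap-selected cluster number under controlled packing.

    Per replicate: draw ``n_clusters`` cluster means from a multivariate
    normal with the (scaled) total-data covariance, then
    ``points_per_cluster`` points per cluster from the within-cluster
    covariance; reduce by PCA to >95% variance; record the
    silhouette-optimal K (argmax over K >= 2) and the gap-selected K.
    Returns a tidy frame (scale, replicate, silhouette_K, gap_K).
    """
    total_cov = np.asarray(total_cov, dtype=float)
    within_cov = np.asarray(within_cov, dtype=float)
    if total_cov.shape != within_cov.shape or total_cov.ndim != 2:
        raise ValueError("covariance matrices must share a square shape")
    try:
        np.linalg.cholesky(total_cov + 1e-10 * np.eye(len(total_cov)))
        np.linalg.cholesky(within_cov + 1e-10 * np.eye(len(within_cov)))
    except np.linalg.LinAlgError as e:
        raise ValueError("covariance matrices must be positive semidefinite") from e

    D = total_cov.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]).spawn(1)[0])
    rows = []
    for scale in scales:
        for rep in range(n_rep):
            means = rng.multivariate_normal(
                np.zeros(D), scale * total_cov, size=n_clusters,
                method="eigh")
            pts = np.vstack([
                rng.multivariate_normal(m, within_cov,
                                        size=points_per_cluster,
                                        method="eigh")
                for m in means])
            Xr = _pca_95_scores(pts)
            sil = {}
            for K in K_grid:
                if K < 2:
                    continue
                lab = KMeans(n_clusters=K, n_init=5,
                             random_state=int(rng.integers(2**31 - 1))
                             ).fit_predict(Xr)
                sil[K] = silhouette_score(Xr, lab)
            sil_K = max(sil, key=sil.get)
            gap_K = gap_statistic(Xr, K_grid=K_grid, n_ref=gap_n_ref,
                                  seed=int(rng.integers(2**31 - 1))).selected_K
            rows.append({"scale": scale, "replicate": rep,
                         "silhouette_K": sil_K, "gap_K": gap_K})
    return pd.DataFrame(rows)
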
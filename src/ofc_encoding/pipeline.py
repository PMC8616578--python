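"""End-to-end orchestration: simulate -> fit -> cluster -> validate ->
metrics -> regress -> report.

Every stage writes tidy CSV/JSON artifacts into a run directory keyed by
a config hash; reruns with the same config and seed are reproducible.
Defaults follow the analysis constants: 50 ms bins, 4 s kernels, M = 9
basis functions, xi in [1e-5, 10], 5 balanced partitions, 500 CPD
shuffles, 500 MI samples, 1000 d-prime shuffles, 5000 gap references,
10000 PAIRS references, 0.95 PCA variance threshold, R^2 > 0 unit
inclusion, CPD outlier cutoff 0.5%.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import clustering, io, metrics, regressions, validation
from .basis import build_basis
from .design import build_design_matrix
from .glm import GLMFit, partition_trials, select_model
from .task import (TaskConfig, generate_session, make_archetypes,
                   simulate_spikes)

__all__ = ["RunConfig", "run_pipeline", "report"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "cluster", "validate", "metrics", "regress",
          "report")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the analysis constants."""

    seed: int = 0
    data_source: str = "synthetic"          # synthetic | deposited
    deposited_path: Optional[str] = None
    n_per_archetype: int = 12
    task: TaskConfig = field(default_factory=TaskConfig)
    stages: Tuple[str, ...] = STAGES

    dt: float = 0.05
    kernel_support: float = 4.0
    xi_range: Tuple[float, float] = (1e-5, 10.0)
    xi_grid: int = 7
    xi_rounds: int = 3
    n_partitions: int = 5
    pca_threshold: float = 0.95
    n_clusters: int = 5
    K_grid: Tuple[int, ...] = tuple(range(1, 16))
    gap_n_ref: int = 5000
    pairs_n_ref: int = 10000
    cpd_shuffles: int = 500
    mi_samples: int = 500
    mi_shuffles: int = 500
    dprime_shuffles: int = 1000
    min_rate_hz: float = 1.0
    cpd_outlier: float = 0.5

    def to_yaml(self, path: Path) -> None:
        d = dataclasses.asdict(self)
        d["task"].pop("flash_count_map", None)
        with open(path, "w") as f:
            yaml.safe_dump(_listify(d), f)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        task = d.pop("task", {})
        if isinstance(task, dict):
            task.pop("flash_count_map", None)
            task = {k: tuple(v) if isinstance(v, list) else v
                    for k, v in task.items()}
            if "click_rate_map" in task and task["click_rate_map"] is not None:
                task["click_rate_map"] = {float(k): float(v) for k, v
                                          in dict(task["click_rate_map"]).items()}
            d["task"] = TaskConfig(**task)
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["task"].pop("flash_count_map", None)
        blob = json.dumps(_listify(d), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _listify(x):
    if isinstance(x, dict):
        return {str(k): _listify(v) for k, v in x.items()}
    if isinstance(x, (tuple, list)):
        return [_listify(v) for v in x]
    if isinstance(x, np.generic):
        return x.item()
    return x


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the enabled stages and return the run directory.

    Stage outputs land in ``<out_dir>/run_<hash>``; later stages refuse
    with a dependency error if an earlier required stage is disabled and
    its artifacts are absent.
    """
    out = Path(out_dir) / f"run_{config.config_hash()}"
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    state: Dict = {}
    exclusions: List[dict] = []

    def need(stage: str):
        if stage not in state:
            raise RuntimeError(
                f"stage dependency missing: {stage!r} must run first")

    basis = build_basis(dt=config.dt, support=config.kernel_support)

    if "simulate" in config.stages:
        if config.data_source == "deposited":
            session, spikes = io.load_deposited(config.deposited_path,
                                                config.min_rate_hz)
            neurons = None
        else:
            session = generate_session(config.task, seed=config.seed)
            neurons = make_archetypes(config.task, seed=config.seed + 1,
                                      n_per_archetype=config.n_per_archetype,
                                      basis=basis)
            spikes = [simulate_spikes(session, nrn, seed=config.seed + 2 + i,
                                      basis=basis)
                      for i, nrn in enumerate(neurons)]
        io.write_session(session, out / "session")
        io.write_spikes_h5(spikes, out / "spikes.h5")
        state["simulate"] = (session, spikes, neurons)
        logger.info("simulated %d trials x %d units", session.n_trials,
                    len(spikes))

    if "fit" in config.stages:
        need("simulate")
        session, spikes, _ = state["simulate"]
        design = build_design_matrix(session, basis=basis)
        scheme = partition_trials(session, seed=config.seed,
                                  n_parts=config.n_partitions)
        fits: List[GLMFit] = []
        rows = []
        for sp in spikes:
            fit = select_model(sp.binned_counts, design, scheme,
                               xi_range=config.xi_range,
                               n_grid=config.xi_grid,
                               n_rounds=config.xi_rounds)
            fits.append(fit)
            rows.append({"unit": sp.unit_id, "xi": fit.xi,
                         "nll_test": fit.nll_test, "r2_test": fit.r2_test,
                         "included": fit.r2_test > 0})
            if fit.r2_test <= 0:
                exclusions.append({"unit": sp.unit_id, "rule": "r2_test<=0"})
        pd.DataFrame(rows).to_csv(out / "glm_fits.csv", index=False)
        state["fit"] = (design, scheme, fits)

    if "cluster" in config.stages:
        need("simulate")
        session, spikes, _ = state["simulate"]
        pm = clustering.psth_matrix(spikes, session)
        fs_psth = clustering.build_psth_feature_space(
            pm, threshold=config.pca_threshold)
        fs_cond = clustering.build_conditional_feature_space(
            spikes, session, threshold=config.pca_threshold)
        res_psth = clustering.kmeans_cluster(fs_psth, config.n_clusters,
                                             seed=config.seed)
        res_cond = clustering.kmeans_cluster(fs_cond, config.n_clusters,
                                             seed=config.seed)
        consistency = clustering.cluster_consistency(res_psth.labels,
                                                     res_cond.labels)
        pd.DataFrame({
            "unit": [spikes[i].unit_id for i in pm.kept],
            "psth_cluster": res_psth.labels,
            "conditional_cluster": res_cond.labels,
        }).to_csv(out / "cluster_labels.csv", index=False)
        np.savetxt(out / "consistency_matrix.csv", consistency, delimiter=",")
        state["cluster"] = (pm, fs_psth, fs_cond, res_psth, res_cond)

    if "validate" in config.stages:
        need("cluster")
        _, fs_psth, fs_cond, res_psth, _ = state["cluster"]
        summary = {}
        rows = []
        for name, fs in (("psth", fs_psth), ("conditional", fs_cond)):
            gc = validation.gap_statistic(fs.M_scores, K_grid=config.K_grid,
                                          n_ref=config.gap_n_ref,
                                          seed=config.seed)
            summary[f"gap_selected_K_{name}"] = gc.selected_K
            for K, g, s in zip(gc.K_grid, gc.gap, gc.se):
                rows.append({"metric": "gap", "space": name, "K": int(K),
                             "value": float(g), "se": float(s)})
            k_pairs = validation.select_pairs_k(
                fs.M_scores.shape[0], fs.k, seed=config.seed, n_draws=20)
            pr = validation.pairs(fs.M_scores, k_pairs,
                                  n_ref=min(config.pairs_n_ref, 500),
                                  seed=config.seed)
            summary[f"pairs_{name}"] = {"k": k_pairs, "PAIRS": pr.pairs,
                                        "p": pr.p_two_sided}
        sep = validation.mahalanobis_separation(fs_psth.M_scores,
                                                res_psth.labels)
        np.savetxt(out / "mahalanobis_psth.csv", sep.D_M, delimiter=",")
        pd.DataFrame(rows).to_csv(out / "validation_curves.csv", index=False)
        with open(out / "validation_summary.json", "w") as f:
            json.dump(_listify(summary), f, indent=2)
        state["validate"] = summary

    if "metrics" in config.stages:
        need("fit")
        need("cluster")
        session, spikes, _ = state["simulate"]
        design, scheme, fits = state["fit"]
        recs = []
        metric_store: Dict[str, List] = {"cpd": [], "dprime": []}
        for sp, fit in zip(spikes, fits):
            if fit.r2_test is not None and fit.r2_test <= 0:
                continue
            for group in metrics.COVARIATE_GROUPS:
                ms = metrics.cpd(fit, design, sp.binned_counts, session,
                                 group, n_shuffles=config.cpd_shuffles,
                                 seed=config.seed,
                                 outlier_threshold=config.cpd_outlier)
                metric_store["cpd"].append((sp.unit_id, group, ms))
                recs.extend(_series_rows(sp.unit_id, ms))
            dm = metrics.dprime(sp, session,
                                n_shuffles=config.dprime_shuffles,
                                seed=config.seed)
            metric_store["dprime"].append((sp.unit_id, "rewardHistory", dm))
            recs.extend(_series_rows(sp.unit_id, dm))
        pd.DataFrame(recs).to_csv(out / "metric_series.csv", index=False)
        state["metrics"] = metric_store

    if "regress" in config.stages:
        need("simulate")
        need("cluster")
        session, spikes, _ = state["simulate"]
        _, _, _, res_psth, _ = state["cluster"]
        rows, classes = [], []
        for sp in spikes:
            er = regressions.epoch_rates(sp, session, epoch="post_choice")
            res = regressions.outcome_adaptation_regression(er, session)
            classes.append(res.classification)
            for name, est in res.coefficients.items():
                rows.append({"unit": sp.unit_id,
                             "analysis": "outcome_adaptation",
                             "coefficient": name, "estimate": est,
                             "p": res.pvalues[name],
                             "classification": res.classification})
        pd.DataFrame(rows).to_csv(out / "regressions.csv", index=False)
        enrich = regressions.cluster_enrichment(classes, res_psth.labels)
        with open(out / "enrichment.json", "w") as f:
            json.dump(_listify({"probability": enrich.probability,
                                "ci95": enrich.ci95,
                                "counts": enrich.counts}), f, indent=2)
        state["regress"] = (classes, enrich)

    if "report" in config.stages:
        need("cluster")
        report(out, state, config)

    pd.DataFrame(exclusions).to_csv(out / "exclusions.csv", index=False)
    return out


def _series_rows(unit: str, ms: metrics.MetricSeries) -> List[dict]:
    return [{
        "unit": unit, "metric": ms.name, "group": ms.group,
        "alignment": ms.alignment, "time_s": float(t), "value": float(v),
        "null_mean": float(nm), "ci_hi": float(ch), "significant": bool(sg),
    } for t, v, nm, ch, sg in zip(ms.time, ms.values, ms.null_mean,
                                  ms.null_ci95, ms.significant)]


def report(run_dir: Path, state: Dict, config: RunConfig) -> None:
    """Figure bundle: cluster PSTHs, consistency heatmap, metric panels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = Path(run_dir) / "figures"
    fig_dir.mkdir(exist_ok=True)
    session, spikes, _ = state["simulate"]
    pm, fs_psth, fs_cond, res_psth, res_cond = state["cluster"]

    # cluster-mean PSTHs sorted by time of peak
    K = res_psth.K
    order = sorted(range(1, K + 1), key=lambda c: np.argmax(
        pm.Z[res_psth.labels == c].mean(axis=0)))
    fig, axes = plt.subplots(K, 1, figsize=(6, 2 * K), sharex=True)
    for ax, c in zip(np.atleast_1d(axes), order):
        sel = pm.Z[res_psth.labels == c]
        ax.plot(pm.time, sel.mean(axis=0))
        ax.fill_between(pm.time,
                        sel.mean(axis=0) - sel.std(axis=0) / np.sqrt(len(sel)),
                        sel.mean(axis=0) + sel.std(axis=0) / np.sqrt(len(sel)),
                        alpha=0.3)
        ax.set_ylabel(f"cluster {c}\n(z)")
    np.atleast_1d(axes)[-1].set_xlabel("time from trial start (s)")
    fig.tight_layout()
    fig.savefig(fig_dir / "cluster_psths.png", dpi=120)
    plt.close(fig)

    cons = clustering.cluster_consistency(res_psth.labels, res_cond.labels)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(cons, vmin=0, vmax=1, cmap="viridis")
    ax.set_xlabel("conditional cluster")
    ax.set_ylabel("PSTH cluster")
    fig.colorbar(im, ax=ax, label="P(cond | PSTH)")
    fig.tight_layout()
    fig.savefig(fig_dir / "consistency.png", dpi=120)
    plt.close(fig)

    # conditional averages: loss vs low (6/12) vs high (24/48) reward
    fig, axes = plt.subplots(1, min(3, len(spikes)), figsize=(12, 3),
                             squeeze=False)
    groups = {"loss": lambda t: t.outcome == "loss",
              "low (6/12 ul)": lambda t: t.V_rewarded in (6.0, 12.0),
              "high (24/48 ul)": lambda t: t.V_rewarded in (24.0, 48.0)}
    for ax, sp in zip(axes[0], spikes[:3]):
        for label, filt in groups.items():
            try:
                t, r = clustering.compute_psth(sp, session, align="t_choice",
                                               window=(-4.0, 4.0),
                                               condition_filter=filt)
                ax.plot(t, r, label=label)
            except ValueError:
                continue
        ax.set_title(sp.unit_id, fontsize=8)
        ax.set_xlabel("time from reward (s)")
    axes[0][0].set_ylabel("rate (Hz)")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(fig_dir / "conditional_averages.png", dpi=120)
    plt.close(fig)

    if "metrics" in state:
        store = state["metrics"]
        for name in ("cpd", "dprime"):
            entries = store.get(name, [])
            if not entries:
                continue
            fig, ax = plt.subplots(figsize=(6, 3))
            for unit, group, ms in entries[:10]:
                v = ms.values.copy()
                v[~ms.significant] = 0.0
                ax.plot(ms.time, v, lw=0.8)
            ax.set_xlabel("time from trial start (s)")
            ax.set_ylabel(name)
            fig.tight_layout()
            fig.savefig(fig_dir / f"{name}_series.png", dpi=120)
            plt.close(fig)
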
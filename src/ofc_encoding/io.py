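"""Reading and writing sessions, spikes, and analysis tables.

Sessions round-trip through a pair of CSVs (trial table + long event
table); spikes are stored in HDF5 (unit -> trial -> spike-time vector)
with a long-format CSV fallback.  A best-effort adapter maps the
publicly deposited dataset (Zenodo 10.5281/zenodo.5592702) onto the
internal data model; its failure never blocks synthetic operation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .task import Session, SpikeData, TaskConfig, Trial

__all__ = [
    "write_session", "read_session",
    "write_spikes_h5", "read_spikes_h5",
    "write_spikes_csv", "read_spikes_csv",
    "load_deposited", "DEPOSIT_DOI",
]

logger = logging.getLogger(__name__)

DEPOSIT_DOI = "10.5281/zenodo.5592702"

_LIST_COLS = ("click_times_L", "click_times_R", "flash_times_L",
              "flash_times_R")


def write_session(session: Session, directory: str | Path) -> None:
    """Write the trial table and the long event table as CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    session.trial_table().to_csv(directory / "trials.csv", index=False)
    session.events_table().to_csv(directory / "events.csv", index=False)


def read_session(directory: str | Path, config: TaskConfig | None = None) -> Session:
    """Rebuild a Session from ``trials.csv`` + ``events.csv``."""
    directory = Path(directory)
    trials_df = pd.read_csv(directory / "trials.csv")
    events = pd.read_csv(directory / "events.csv")
    ev_by_trial = {k: g for k, g in events.groupby("trial")}
    trials: List[Trial] = []
    for _, row in trials_df.iterrows():
        g = ev_by_trial.get(int(row["index"]), pd.DataFrame(
            columns=["event_name", "time_s"]))

        def times(name: str) -> np.ndarray:
            return g.loc[g["event_name"] == name, "time_s"].to_numpy()

        trials.append(Trial(
            index=int(row["index"]), t_start=float(row["t_start"]),
            click_times_L=times("click_L"), click_times_R=times("click_R"),
            flash_times_L=times("flash_L"), flash_times_R=times("flash_R"),
            t_go=float(row["t_go"]),
            t_exit_center=float(row["t_exit_center"]),
            t_choice=float(row["t_choice"]),
            choice=row["choice"], chose_safe=row["chose_safe"],
            outcome=row["outcome"],
            V_left=float(row["V_left"]), V_right=float(row["V_right"]),
            p_left=float(row["p_left"]), p_right=float(row["p_right"]),
            V_rewarded=float(row["V_rewarded"]),
            EV_left=float(row["EV_left"]), EV_right=float(row["EV_right"]),
            prev_outcome=row["prev_outcome"],
            prev_reward_rate=float(row["prev_reward_rate"]),
            session_progress=float(row["session_progress"]),
        ))
    return Session(trials=trials, config=config or TaskConfig(
        n_trials=len(trials)))


def write_spikes_h5(spike_list: Sequence[SpikeData], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for sp in spike_list:
            g = f.create_group(sp.unit_id)
            g.create_dataset("binned_counts", data=sp.binned_counts,
                             compression="gzip")
            g.create_dataset("bin_edges", data=sp.bin_edges)
            tg = g.create_group("trials")
            for i, st in enumerate(sp.spike_times):
                tg.create_dataset(str(i), data=st)


def read_spikes_h5(path: str | Path) -> List[SpikeData]:
    out = []
    with h5py.File(path, "r") as f:
        for unit_id in f:
            g = f[unit_id]
            n = g["binned_counts"].shape[0]
            st = [g["trials"][str(i)][()] for i in range(n)]
            out.append(SpikeData(unit_id=unit_id, spike_times=st,
                                 binned_counts=g["binned_counts"][()],
                                 bin_edges=g["bin_edges"][()]))
    return out


def write_spikes_csv(spike_list: Sequence[SpikeData], path: str | Path) -> None:
    """Long-format plain-text fallback (unit, trial, spike_time_s)."""
    recs = []
    for sp in spike_list:
        for i, st in enumerate(sp.spike_times):
            for t in st:
                recs.append((sp.unit_id, i, t))
    pd.DataFrame(recs, columns=["unit", "trial", "spike_time_s"]).to_csv(
        path, index=False)


def read_spikes_csv(path: str | Path, n_trials: int,
                    window: Tuple[float, float] = (-2.0, 6.0),
                    dt: float = 0.05) -> List[SpikeData]:
    df = pd.read_csv(path)
    n_bins = int(round((window[1] - window[0]) / dt))
    edges = window[0] + np.arange(n_bins + 1) * dt
    out = []
    for unit, g in df.groupby("unit"):
        st = [np.sort(g.loc[g["trial"] == i, "spike_time_s"].to_numpy())
              for i in range(n_trials)]
        counts = np.vstack([np.histogram(s, bins=edges)[0] for s in st])
        out.append(SpikeData(unit_id=str(unit), spike_times=st,
                             binned_counts=counts, bin_edges=edges))
    return out


def load_deposited(path: str | Path, min_rate_hz: float = 1.0
                   ) -> Tuple[Session, List[SpikeData]]:
    """Adapter for the deposited source data (user-downloaded archive).

    Maps deposited behavior/physiology tables onto the internal Session
    and SpikeData model, applying the 1 Hz minimum-mean-rate inclusion
    rule.  The expected layout is ``trials.csv``/``events.csv`` plus
    ``spikes.h5`` (or ``spikes.csv``) produced by converting the archive;
    schema mismatches are reported field by field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"deposited dataset not found at {path}; download the archive "
            f"from DOI {DEPOSIT_DOI} and convert it to the documented "
            "trial/event/spike layout")
    problems = []
    if not (path / "trials.csv").exists():
        problems.append("missing trials.csv")
    if not (path / "events.csv").exists():
        problems.append("missing events.csv")
    has_h5 = (path / "spikes.h5").exists()
    if not has_h5 and not (path / "spikes.csv").exists():
        problems.append("missing spikes.h5 / spikes.csv")
    if problems:
        raise ValueError("deposited data schema mismatch: " +
                         "; ".join(problems))
    session = read_session(path)
    spikes = (read_spikes_h5(path / "spikes.h5") if has_h5
              else read_spikes_csv(path / "spikes.csv", session.n_trials))

    kept = []
    for sp in spikes:
        total_time = sp.binned_counts.size * sp.dt
        rate = sp.binned_counts.sum() / total_time
        if rate >= min_rate_hz:
            kept.append(sp)
        else:
            logger.info("excluding unit %s: mean rate %.2f Hz < %.1f Hz",
                        sp.unit_id, rate, min_rate_hz)
    logger.info("loaded %d units (%d excluded by the %.1f Hz rule)",
                len(kept), len(spikes) - len(kept), min_rate_hz)
    if len(kept) != 659:
        logger.warning("unit count %d differs from the deposit's expected "
                       "659 well-isolated single units", len(kept))
    return session, kept
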
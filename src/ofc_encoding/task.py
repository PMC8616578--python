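"""Synthetic cued-gamble sessions and ground-truth Poisson-GLM neurons.

Emulates a rodent risky-choice task: the rat pokes a center port, hears
Poisson click trains whose rates convey the water volume offered at each
side port, sees light flashes whose count conveys reward probability,
then after a go cue exits the center port and chooses a side.  One side
is always safe (p = 1), the other risky (p < 1).  Outcomes are win,
loss, or opt-out.  Neurons are simulated from an exponential-link
Poisson GLM whose kernels live in the package's raised-cosine basis,
with five planted response archetypes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .basis import BasisSet, build_basis

__all__ = [
    "TaskConfig",
    "Trial",
    "Session",
    "GroundTruthNeuron",
    "SpikeData",
    "generate_session",
    "make_archetypes",
    "simulate_spikes",
    "ARCHETYPE_NAMES",
]

#: default mapping from offered volume (µl) to click rate (Hz); monotone linear
DEFAULT_CLICK_RATES = {6.0: 10.0, 12.0: 20.0, 24.0: 30.0, 48.0: 40.0}


def default_flash_count(p: float) -> int:
    """Flash count conveying reward probability (monotone linear, 2..10)."""
    return int(round(2 + 8 * p))


@dataclass
class TaskConfig:
    """Parameters of the synthetic task (durations in seconds)."""

    n_trials: int = 300
    volumes: tuple = (6.0, 12.0, 24.0, 48.0)
    probability_levels: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    p_opt_out: float = 0.05
    pre_flash_range: tuple = (0.0, 0.35)
    post_flash_range: tuple = (0.0, 0.5)
    cue_period_range: tuple = (2.5, 3.0)
    flash_spacing: float = 0.25
    flash_duration: float = 0.02
    click_rate_map: Dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_CLICK_RATES))
    flash_count_map: Callable[[float], int] = default_flash_count
    movement_time_range: tuple = (0.15, 0.45)
    exit_latency_range: tuple = (0.05, 0.25)
    iti_range: tuple = (2.0, 4.0)
    choice_beta: float = 0.05  # logistic sensitivity of choice to ΔEV (1/µl)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not 0.0 <= self.p_opt_out <= 1.0:
            raise ValueError("p_opt_out must lie in [0, 1]")
        for p in self.probability_levels:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability level {p} outside [0, 1]")
        for name in ("flash_spacing", "flash_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pre_flash_range", "post_flash_range", "cue_period_range",
                     "movement_time_range", "exit_latency_range", "iti_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid interval for {name}: ({lo}, {hi})")
        if self.cue_period_range[0] <= 0:
            raise ValueError("cue period must be positive")
        missing = set(self.volumes) - set(self.click_rate_map)
        if missing:
            raise ValueError(f"click_rate_map missing volumes: {missing}")


@dataclass
class Trial:
    """One trial: event times are absolute session times in seconds."""

    index: int
    t_start: float
    click_times_L: np.ndarray
    click_times_R: np.ndarray
    flash_times_L: np.ndarray
    flash_times_R: np.ndarray
    t_go: float
    t_exit_center: float
    t_choice: float
    choice: str                # {"left", "right"}
    chose_safe: str            # {"safe", "risky"}
    outcome: str               # {"win", "loss", "opt_out"}
    V_left: float
    V_right: float
    p_left: float
    p_right: float
    V_rewarded: float
    EV_left: float
    EV_right: float
    prev_outcome: str          # {"win", "loss", "opt_out", "none"}
    prev_reward_rate: float    # mean rewarded volume over all previous trials
    session_progress: float    # trial index normalized to [0, 1]

    @property
    def V_chosen(self) -> float:
        return self.V_left if self.choice == "left" else self.V_right

    @property
    def p_chosen(self) -> float:
        return self.p_left if self.choice == "left" else self.p_right

    @property
    def rpe(self) -> float:
        """Reward prediction error: received volume minus chosen EV."""
        return self.V_rewarded - self.p_chosen * self.V_chosen


@dataclass
class Session:
    """Ordered trials plus the generating configuration."""

    trials: List[Trial]
    config: TaskConfig

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    def trial_table(self) -> pd.DataFrame:
        """One row per trial; click/flash times summarized as counts."""
        rows = []
        for tr in self.trials:
            d = dataclasses.asdict(tr)
            for side in ("L", "R"):
                d[f"n_clicks_{side}"] = len(d.pop(f"click_times_{side}"))
                d[f"n_flashes_{side}"] = len(d.pop(f"flash_times_{side}"))
            rows.append(d)
        return pd.DataFrame(rows)

    def events_table(self) -> pd.DataFrame:
        """Long-format event table (trial, event_name, time_s)."""
        recs = []
        for tr in self.trials:
            recs.append((tr.index, "trial_start", tr.t_start))
            for t in tr.click_times_L:
                recs.append((tr.index, "click_L", t))
            for t in tr.click_times_R:
                recs.append((tr.index, "click_R", t))
            for t in tr.flash_times_L:
                recs.append((tr.index, "flash_L", t))
            for t in tr.flash_times_R:
                recs.append((tr.index, "flash_R", t))
            recs.append((tr.index, "go_cue", tr.t_go))
            recs.append((tr.index, "exit_center", tr.t_exit_center))
            recs.append((tr.index, "side_port_entry", tr.t_choice))
        return pd.DataFrame(recs, columns=["trial", "event_name", "time_s"])


def _rng_streams(seed: int, names: Sequence[str]) -> Dict[str, np.random.Generator]:
    """Fan a single seed out to named independent substreams."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_session(config: TaskConfig, seed: Optional[int] = None) -> Session:
    """Generate one synthetic session.

    Event times are strictly ordered within each trial
    (t_start < t_go < t_exit_center < t_choice); flashes fall on the
    250 ms grid after a uniform pre-flash interval; clicks are Poisson
    at the rate mapped from the offered volume; outcomes are drawn
    independently per trial with P(win) equal to the chosen side's
    reward probability.  History fields depend only on earlier trials.
    """
    if seed is None:
        seed = config.seed
    rng = _rng_streams(seed, ["session"])["session"]

    risky_levels = [p for p in config.probability_levels if p < 1.0]
    if not risky_levels:
        risky_levels = [1.0]

    trials: List[Trial] = []
    t_cursor = 0.0
    n_rewarded_sum = 0.0
    for i in range(config.n_trials):
        t_start = t_cursor + rng.uniform(*config.iti_range)
        cue_period = rng.uniform(*config.cue_period_range)
        pre_flash = rng.uniform(*config.pre_flash_range)
        post_flash = rng.uniform(*config.post_flash_range)

        safe_side = "left" if rng.random() < 0.5 else "right"
        p_risky = float(rng.choice(risky_levels))
        p_left, p_right = (1.0, p_risky) if safe_side == "left" else (p_risky, 1.0)
        V_left = float(rng.choice(config.volumes))
        V_right = float(rng.choice(config.volumes))

        clicks = {}
        for side, V in (("L", V_left), ("R", V_right)):
            rate = config.click_rate_map[V]
            n = rng.poisson(rate * cue_period)
            clicks[side] = t_start + np.sort(rng.uniform(0.0, cue_period, size=n))

        flashes = {}
        flash_window_end = cue_period - post_flash
        for side, p in (("L", p_left), ("R", p_right)):
            n_fl = max(0, int(config.flash_count_map(p)))
            grid = pre_flash + np.arange(n_fl) * config.flash_spacing
            grid = grid[grid + config.flash_duration <= flash_window_end]
            flashes[side] = t_start + grid

        t_go = t_start + cue_period
        t_exit = t_go + rng.uniform(*config.exit_latency_range)
        t_choice = t_exit + rng.uniform(*config.movement_time_range)

        EV_left, EV_right = p_left * V_left, p_right * V_right
        p_choose_left = 1.0 / (1.0 + np.exp(-config.choice_beta * (EV_left - EV_right)))
        choice = "left" if rng.random() < p_choose_left else "right"
        chose_safe = "safe" if choice == safe_side else "risky"

        if rng.random() < config.p_opt_out:
            outcome = "opt_out"
            V_rewarded = 0.0
        else:
            p_chosen = p_left if choice == "left" else p_right
            if rng.random() < p_chosen:
                outcome = "win"
                V_rewarded = V_left if choice == "left" else V_right
            else:
                outcome = "loss"
                V_rewarded = 0.0

        prev_outcome = trials[-1].outcome if trials else "none"
        prev_rate = n_rewarded_sum / i if i > 0 else 0.0
        progress = i / (config.n_trials - 1) if config.n_trials > 1 else 0.0

        trials.append(Trial(
            index=i, t_start=t_start,
            click_times_L=clicks["L"], click_times_R=clicks["R"],
            flash_times_L=flashes["L"], flash_times_R=flashes["R"],
            t_go=t_go, t_exit_center=t_exit, t_choice=t_choice,
            choice=choice, chose_safe=chose_safe, outcome=outcome,
            V_left=V_left, V_right=V_right, p_left=p_left, p_right=p_right,
            V_rewarded=V_rewarded, EV_left=EV_left, EV_right=EV_right,
            prev_outcome=prev_outcome, prev_reward_rate=prev_rate,
            session_progress=progress,
        ))
        n_rewarded_sum += V_rewarded
        t_cursor = t_choice

    return Session(trials=trials, config=config)


# ---------------------------------------------------------------------------
# Ground-truth neurons

ARCHETYPE_NAMES = (
    "trial_start_burst",
    "persistent_cue",
    "prechoice_reward_history",
    "choice_locked",
    "reward_locked",
)


@dataclass
class GroundTruthNeuron:
    """A simulated unit defined by basis weights per task variable."""

    archetype: str
    kernel_weights: Dict[str, np.ndarray]
    background: float          # log mean counts/bin (theta_0)
    unit_id: str

    def theta_vector(self, variables: Sequence[str], n_basis: int) -> np.ndarray:
        """Flatten kernel weights into the design order (theta_0 last)."""
        theta = np.zeros(len(variables) * n_basis + 1)
        for v, w in self.kernel_weights.items():
            if v not in variables:
                raise KeyError(f"unknown task variable in kernel map: {v}")
            j = list(variables).index(v)
            theta[j * n_basis:(j + 1) * n_basis] = w
        theta[-1] = self.background
        return theta


@dataclass
class SpikeData:
    """Per-unit spike times and binned counts on per-trial windows."""

    unit_id: str
    spike_times: List[np.ndarray]     # per trial, seconds relative to t_start
    binned_counts: np.ndarray         # (n_trials, n_bins), 50 ms bins
    bin_edges: np.ndarray             # seconds relative to t_start

    @property
    def n_trials(self) -> int:
        return self.binned_counts.shape[0]

    @property
    def dt(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def _w(onset: np.ndarray = 0, early: float = 0.0, mid: float = 0.0,
       late: float = 0.0) -> np.ndarray:
    """Shorthand for 9-dim weight vectors: [exp x2, cos peaks 25ms..2s x7]."""
    w = np.zeros(9)
    w[0:2] = onset
    w[2:4] += early     # cosine peaks ~25-65 ms
    w[4:7] += mid       # ~0.17-1.2 s
    w[7:9] += late      # ~1.26-2 s
    return w


def make_archetypes(
    config: Optional[TaskConfig] = None,
    seed: int = 0,
    n_per_archetype: int = 1,
    background_rate_hz: float = 5.0,
    jitter: float = 0.1,
    basis: Optional[BasisSet] = None,
    include_null: bool = False,
) -> List[GroundTruthNeuron]:
    """Build ground-truth neurons, ``n_per_archetype`` per archetype.

    Five archetypes mirror canonical orbitofrontal response profiles:

    1. ``trial_start_burst`` — transient burst at trial initiation.
    2. ``persistent_cue`` — sustained cue-period activity driven by
       click/flash streams.
    3. ``prechoice_reward_history`` — the only archetype whose previous-
       outcome kernels differ between previous wins and losses, with mass
       both at trial start and at long lags (re-emerging before the
       choice), the planted positive for reward-history recovery tests.
    4. ``choice_locked`` — lateralized response at center-port exit.
    5. ``reward_locked`` — differential win/loss response at outcome.

    All archetypes carry (possibly condition-symmetric) outcome and
    choice kernels.  Weights are jittered multiplicatively across units
    (lognormal, sigma = ``jitter``).  ``include_null`` appends one
    all-zero-kernel unit (constant-rate Poisson).
    """
    if n_per_archetype < 1:
        raise ValueError("need at least one neuron per archetype")
    if basis is None:
        basis = build_basis()
    dt = basis.dt
    theta0 = float(np.log(background_rate_hz * dt))
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    base_maps: Dict[str, Dict[str, np.ndarray]] = {
        "trial_start_burst": {
            "prevWin": _w(onset=1.2, early=0.9),
            "prevLoss": _w(onset=1.2, early=0.9),
            "prevOptOut": _w(onset=1.2, early=0.9),
            "win": _w(early=0.3), "loss": _w(early=0.3),
            "leftChoice": _w(early=0.2), "rightChoice": _w(early=0.2),
        },
        # stimulus kernels are small per event: click trains run at tens of
        # Hz, so the summed log-rate elevation is rate * integral(k) per side
        "persistent_cue": {
            "leftClick": _w(onset=0.08),
            "rightClick": _w(onset=0.08),
            "leftFlash": _w(early=0.1, mid=0.05),
            "rightFlash": _w(early=0.1, mid=0.05),
            "prevWin": _w(mid=0.2), "prevLoss": _w(mid=0.2),
            "prevOptOut": _w(mid=0.2),
            "win": _w(early=0.25), "loss": _w(early=0.25),
            "leftChoice": _w(early=0.2), "rightChoice": _w(early=0.2),
        },
        "prechoice_reward_history": {
            # differential previous-outcome kernels: early mass at trial
            # start plus late mass (~1.3-2 s lags) reappearing pre-choice
            "prevWin": _w(onset=0.5, early=0.7, late=0.9),
            "prevLoss": _w(onset=0.1, early=0.1, late=0.1),
            "prevOptOut": _w(onset=0.1, early=0.1, late=0.1),
            "win": _w(early=0.5), "loss": _w(early=0.2),
            "leftChoice": _w(early=0.35), "rightChoice": _w(early=0.35),
        },
        "choice_locked": {
            "leftChoice": _w(onset=0.6, early=1.0),
            "rightChoice": _w(early=0.15),
            "prevWin": _w(early=0.2), "prevLoss": _w(early=0.2),
            "prevOptOut": _w(early=0.2),
            "win": _w(early=0.3), "loss": _w(early=0.3),
        },
        "reward_locked": {
            "win": _w(onset=0.7, early=1.1),
            "loss": _w(early=-0.3),
            "prevWin": _w(early=0.15), "prevLoss": _w(early=0.15),
            "prevOptOut": _w(early=0.15),
            "leftChoice": _w(early=0.25), "rightChoice": _w(early=0.25),
        },
    }

    neurons: List[GroundTruthNeuron] = []
    for arch in ARCHETYPE_NAMES:
        for i in range(n_per_archetype):
            scale = float(np.exp(rng.normal(0.0, jitter)))
            weights = {v: w * scale for v, w in base_maps[arch].items()}
            neurons.append(GroundTruthNeuron(
                archetype=arch, kernel_weights=weights,
                background=theta0 + rng.normal(0.0, jitter),
                unit_id=f"{arch}_{i:03d}",
            ))
    if include_null:
        neurons.append(GroundTruthNeuron(
            archetype="null", kernel_weights={}, background=theta0,
            unit_id="null_000"))
    return neurons


def simulate_spikes(
    session: Session,
    neuron: GroundTruthNeuron,
    seed: int = 0,
    basis: Optional[BasisSet] = None,
    window: tuple = (-2.0, 6.0),
    max_rate_hz: float = 500.0,
) -> SpikeData:
    """Simulate spike counts from the generative Poisson GLM.

    Counts in each 50 ms bin are Poisson with mean exp(X theta + theta_0),
    where X is the session design matrix in the package basis.  Rates
    exceeding ``max_rate_hz`` raise (overflow is reported, never clipped).
    Spike times are placed uniformly within their bins.
    """
    from .design import build_design_matrix

    if basis is None:
        basis = build_basis()
    design = build_design_matrix(session, basis=basis, window=window)
    theta = neuron.theta_vector(design.variables, basis.n_basis)
    eta = design.X @ theta[:-1] + theta[-1]
    lam = np.exp(eta)  # mean counts per bin
    if np.max(lam) > max_rate_hz * basis.dt:
        raise OverflowError(
            f"simulated rate {np.max(lam) / basis.dt:.1f} Hz exceeds "
            f"max_rate_hz={max_rate_hz}; kernel weights too large")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]).spawn(1)[0])
    counts = rng.poisson(lam).astype(np.int64)
    counts_mat = counts.reshape(session.n_trials, design.n_bins)

    edges = window[0] + np.arange(design.n_bins + 1) * basis.dt
    spike_times = []
    for tr in range(session.n_trials):
        times = []
        nz = np.nonzero(counts_mat[tr])[0]
        for b in nz:
            times.append(edges[b] + rng.uniform(0, basis.dt, size=counts_mat[tr, b]))
        spike_times.append(np.sort(np.concatenate(times)) if times
                           else np.empty(0))

    return SpikeData(unit_id=neuron.unit_id, spike_times=spike_times,
                     binned_counts=counts_mat, bin_edges=edges)
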
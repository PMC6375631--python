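"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline is exercised on data produced here:
primer-extension time courses drawn from the closed-form dynamic-deactivation
model, exponential relative-activity decay series, and two-state alternating
bound/unbound smFRET trajectories with exponential dwells, a fixed bound-state
FRET efficiency, additive per-channel Gaussian intensity noise and optional
photobleach truncation.  Generators are deterministic given a seed, and the
trajectory generator returns its true event list alongside the intensities so
detection bias is directly measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deactivation import ActivitySeries, TimeCourse, model_pe
from .events import FretTrajectory

__all__ = [
    "ExtensionSimParams",
    "ActivitySimParams",
    "FretSimParams",
    "TrueEvent",
    "gen_extension_timecourse",
    "gen_extension_replicates",
    "gen_activity_decay",
    "gen_fret_trajectories",
    "true_events_frame",
]


def _check_times(times: np.ndarray, allow_zero_start: bool = True) -> None:
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-d array")
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    bad = np.flatnonzero(np.diff(times) <= 0)
    if bad.size:
        raise ValueError(f"times must be strictly increasing; offending index {bad[0] + 1}")


@dataclass(frozen=True)
class ExtensionSimParams:
    """Ground truth for a primer-extension time course.

    ``k`` is the pseudo-first-order synthesis rate and ``D`` the dynamic
    deactivation rate, both min^-1; ``noise_sd`` is additive Gaussian noise on
    the fraction-extended scale, applied independently per replicate.
    """

    k: float
    D: float
    times: np.ndarray
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.k < 0 or self.D < 0:
            raise ValueError("k and D must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        _check_times(self.times)


@dataclass(frozen=True)
class ActivitySimParams:
    """Ground truth for a static-deactivation relative-activity series."""

    rate: float
    times: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.rate < 0:
            raise ValueError("decay rate must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        _check_times(self.times)
        if self.times[0] != 0:
            raise ValueError("activity series must start at t = 0")


@dataclass(frozen=True)
class FretSimParams:
    """Ground truth for two-state alternating binding trajectories.

    Dwell times are exponential with means ``tau_bound``/``tau_unbound``
    (seconds); trajectories start unbound (the polymerase is added after
    acquisition starts).  In the bound state the acceptor carries
    ``I_total * E_bound`` and the donor ``I_total * (1 - E_bound)``; unbound
    frames sit at ``unbound_donor`` (defaults to ``I_total``) in the donor
    channel and ``background_acceptor`` (defaults to 0) in the acceptor
    channel.  ``noise_sd`` is per-channel additive Gaussian noise.  When
    ``bleach_tau`` is set the record is truncated at an exponential
    photobleach time.
    """

    tau_bound: float = 6.1
    tau_unbound: float = 17.0
    E_bound: float = 0.7
    frame_dt: float = 0.3
    duration: float = 180.0
    I_total: float = 300.0
    noise_sd: float = 0.0
    bleach_tau: float | None = None
    n_traj: int = 1
    seed: int = 0
    unbound_donor: float | None = None
    background_acceptor: float = 0.0

    def __post_init__(self):
        if self.tau_bound <= 0:
            raise ValueError("tau_bound must be positive")
        if not (self.tau_unbound > 0):  # inf allowed: never binds
            raise ValueError("tau_unbound must be positive")
        if not (0.0 < self.E_bound < 1.0):
            raise ValueError("E_bound must lie strictly between 0 and 1")
        if self.frame_dt <= 0 or self.duration <= 0:
            raise ValueError("frame_dt and duration must be positive")
        n = self.duration / self.frame_dt
        if abs(n - round(n)) * self.frame_dt > self.frame_dt:
            raise ValueError("frame_dt must divide duration within one frame")
        if self.bleach_tau is not None and self.bleach_tau <= 0:
            raise ValueError("bleach_tau must be positive when set")
        if self.n_traj < 1:
            raise ValueError("n_traj must be at least 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_dt))

    @property
    def donor_unbound_level(self) -> float:
        return self.I_total if self.unbound_donor is None else self.unbound_donor


@dataclass(frozen=True)
class TrueEvent:
    """A ground-truth dwell interval, including dwells shorter than a frame."""

    traj_id: str
    start_s: float
    end_s: float
    state: str  # "bound" | "unbound"

    @property
    def dwell_s(self) -> float:
        return self.end_s - self.start_s


def gen_extension_replicates(params: ExtensionSimParams) -> pd.DataFrame:
    """Per-replicate extension fractions as a tidy frame.

    Columns ``time_min, pe_fraction, replicate_id``; the noiseless model value
    plus independent Gaussian noise, clipped to [0, 1].
    """
    rng = np.random.default_rng(params.seed)
    clean = model_pe(params.times, params.k, params.D)
    rows = []
    for rep in range(params.n_replicates):
        noise = rng.normal(0.0, params.noise_sd, size=params.times.size) \
            if params.noise_sd > 0 else np.zeros(params.times.size)
        pe = np.clip(np.atleast_1d(clean) + noise, 0.0, 1.0)
        rows.append(pd.DataFrame({
            "time_min": params.times, "pe_fraction": pe, "replicate_id": rep,
        }))
    return pd.concat(rows, ignore_index=True)


def gen_extension_timecourse(params: ExtensionSimParams) -> TimeCourse:
    """Extension time course averaged over replicates (SD attached if n >= 2)."""
    reps = gen_extension_replicates(params)
    g = reps.groupby("time_min", sort=True)["pe_fraction"]
    pe = g.mean().to_numpy()
    sd = g.std(ddof=1).to_numpy() if params.n_replicates >= 2 else None
    return TimeCourse(times=params.times, pe=pe, pe_sd=sd)


def gen_activity_decay(params: ActivitySimParams) -> ActivitySeries:
    """Relative-activity decay A(t) = exp(-rate t) + noise, clipped to [0, 1.05]."""
    rng = np.random.default_rng(params.seed)
    clean = np.exp(-params.rate * params.times)
    noise = rng.normal(0.0, params.noise_sd, size=params.times.size) \
        if params.noise_sd > 0 else 0.0
    return ActivitySeries(times=params.times,
                          rel_activity=np.clip(clean + noise, 0.0, 1.05))


def _draw_dwell(rng: np.random.Generator, mean: float) -> float:
    return np.inf if np.isinf(mean) else float(rng.exponential(mean))


def _simulate_state_path(rng, params: FretSimParams, t_end: float) -> list[TrueEvent]:
    """Alternating-renewal path starting unbound, truncated at t_end."""
    events: list[TrueEvent] = []
    t, bound = 0.0, False
    while t < t_end:
        mean = params.tau_bound if bound else params.tau_unbound
        dwell = _draw_dwell(rng, mean)
        end = min(t + dwell, t_end)
        if end > t:
            events.append(TrueEvent(traj_id="", start_s=t, end_s=end,
                                    state="bound" if bound else "unbound"))
        t = t + dwell
        bound = not bound
    return events


def gen_fret_trajectories(params: FretSimParams):
    """Generate noisy two-state trajectories plus their ground-truth events.

    Returns ``(trajectories, true_events)``: a list of
    :class:`~polvmut.events.FretTrajectory` and a flat list of
    :class:`TrueEvent` covering every dwell (including sub-frame dwells that
    detection cannot resolve).  A frame is bound when its center time falls
    inside a bound interval.
    """
    rng = np.random.default_rng(params.seed)
    trajs: list[FretTrajectory] = []
    truth: list[TrueEvent] = []
    n_frames_full = params.n_frames
    frame_times = np.arange(n_frames_full) * params.frame_dt
    centers = frame_times + params.frame_dt / 2.0

    for i in range(params.n_traj):
        tid = f"traj{i:04d}"
        t_end = params.duration
        if params.bleach_tau is not None:
            t_end = min(t_end, float(rng.exponential(params.bleach_tau)))
        path = _simulate_state_path(rng, params, t_end)
        truth.extend(TrueEvent(tid, ev.start_s, ev.end_s, ev.state) for ev in path)

        keep = centers < t_end if t_end < params.duration else slice(None)
        tt = frame_times[keep]
        cc = centers[keep]
        n = tt.size
        if n == 0:
            # bleached before the first frame center: emit an empty record
            trajs.append(FretTrajectory(tid, np.empty(0), np.empty(0), np.empty(0)))
            continue
        bound_starts = np.array([ev.start_s for ev in path if ev.state == "bound"])
        bound_ends = np.array([ev.end_s for ev in path if ev.state == "bound"])
        if bound_starts.size:
            idx = np.searchsorted(bound_starts, cc, side="right") - 1
            in_bound = (idx >= 0) & (cc < bound_ends[np.clip(idx, 0, None)])
        else:
            in_bound = np.zeros(n, dtype=bool)

        i_d = np.where(in_bound, params.I_total * (1.0 - params.E_bound),
                       params.donor_unbound_level).astype(float)
        i_a = np.where(in_bound, params.I_total * params.E_bound,
                       params.background_acceptor).astype(float)
        if params.noise_sd > 0:
            i_d = i_d + rng.normal(0.0, params.noise_sd, size=n)
            i_a = i_a + rng.normal(0.0, params.noise_sd, size=n)
        trajs.append(FretTrajectory(tid, tt, i_d, i_a))
    return trajs, truth


def true_events_frame(truth: list[TrueEvent]) -> pd.DataFrame:
    """Ground-truth events as a frame with columns traj_id, start_s, end_s, state."""
    return pd.DataFrame({
        "traj_id": [e.traj_id for e in truth],
        "start_s": [e.start_s for e in truth],
        "end_s": [e.end_s for e in truth],
        "state": [e.state for e in truth],
    })
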
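"""smFRET trajectory idealization: efficiencies, binding events, dwell samples.

A trajectory is a pair of per-frame donor/acceptor intensities on a uniform
time grid.  Per-frame FRET efficiency E = I_A / (I_D + I_A) reports whether
the acceptor-labelled polymerase is bound near the donor-labelled DNA; bound
intervals are idealized as maximal runs of consecutive frames with E at or
above a threshold.  Runs touching the start or end of the record are flagged
censored — the true dwell extends beyond what was observed — and are excluded
from dwell-time samples by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FretTrajectory",
    "BindingEvent",
    "EventSet",
    "fret_efficiency",
    "detect_events",
    "dwell_times",
    "rebind_times",
    "efficiency_histogram",
    "ThresholdEventDetector",
]


@dataclass(frozen=True)
class FretTrajectory:
    """Per-frame donor/acceptor intensities on a uniform time grid (seconds)."""

    traj_id: str
    times: np.ndarray
    I_D: np.ndarray
    I_A: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.I_D, dtype=float)
        a = np.asarray(self.I_A, dtype=float)
        for name, arr in (("times", t), ("I_D", d), ("I_A", a)):
            if arr.ndim != 1:
                raise ValueError(f"{name} must be 1-d")
        if not (t.shape == d.shape == a.shape):
            raise ValueError("times, I_D and I_A must have equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if dt.min() <= 0:
                raise ValueError("times must be strictly increasing")
            if (dt.max() - dt.min()) > 0.01 * dt.mean():
                raise ValueError("frame spacing must be constant within 1%")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "I_D", d)
        object.__setattr__(self, "I_A", a)

    @property
    def frame_dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("frame interval undefined for < 2 frames")
        return float(np.mean(np.diff(self.times)))

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_dt


@dataclass(frozen=True)
class BindingEvent:
    """An idealized bound interval.

    ``start_s`` is the time stamp of the first qualifying frame and ``end_s``
    is ``start_s + n_frames * frame_dt`` so that ``dwell_s = end_s - start_s``
    counts whole frames (closed on both ends).
    """

    traj_id: str
    start_s: float
    end_s: float
    mean_E: float
    left_censored: bool
    right_censored: bool
    frame_E: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("events must have positive dwell")
        if not (0.0 <= self.mean_E <= 1.0):
            raise ValueError("mean_E must lie in [0, 1]")

    @property
    def dwell_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def censored(self) -> bool:
        return self.left_censored or self.right_censored

    @property
    def n_frames(self) -> int:
        return int(np.asarray(self.frame_E).size)


@dataclass
class EventSet:
    """Ordered, non-overlapping binding events across one or more trajectories."""

    events: list[BindingEvent]
    meta: dict[str, dict]  # traj_id -> {"frame_dt": ..., "duration": ...}

    def __post_init__(self):
        for tid in {e.traj_id for e in self.events}:
            evs = [e for e in self.events if e.traj_id == tid]
            starts = [e.start_s for e in evs]
            if starts != sorted(starts):
                raise ValueError(f"events of trajectory {tid} are not time-ordered")
            for a, b in zip(evs, evs[1:]):
                if b.start_s < a.end_s:
                    raise ValueError(f"overlapping events in trajectory {tid}")

    def __len__(self) -> int:
        return len(self.events)

    def by_trajectory(self) -> dict[str, list[BindingEvent]]:
        out: dict[str, list[BindingEvent]] = {}
        for ev in self.events:
            out.setdefault(ev.traj_id, []).append(ev)
        return out

    @staticmethod
    def merge(sets: list["EventSet"]) -> "EventSet":
        events = [e for s in sets for e in s.events]
        meta = {k: v for s in sets for k, v in s.meta.items()}
        return EventSet(events=events, meta=meta)


def fret_efficiency(I_D, I_A):
    """Per-frame FRET efficiency E = I_A / (I_D + I_A), clipped to [0, 1].

    Frames with nonpositive total intensity are invalid and returned as NaN;
    event logic treats them as not bound.
    """
    d = np.asarray(I_D, dtype=float)
    a = np.asarray(I_A, dtype=float)
    total = d + a
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(total > 0, a / np.where(total > 0, total, 1.0), np.nan)
    e = np.clip(e, 0.0, 1.0)
    if np.ndim(I_D) == 0 and np.ndim(I_A) == 0:
        val = float(e)
        if total <= 0:
            raise ValueError("I_D + I_A must be positive")
        return val
    return e


def _bound_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


class ThresholdEventDetector(TransformerMixin, BaseEstimator):
    """Threshold-run binding-event detector.

    Deterministic replacement for image-analysis event pickers: maximal runs
    of at least ``min_frames`` consecutive frames with FRET efficiency at or
    above ``threshold`` become binding events.  Runs touching the first or
    last frame are censored.  When ``subtract_background`` is set, the
    acceptor channel is corrected by the per-trajectory median acceptor
    intensity over unbound frames (estimated in a first thresholding pass)
    before efficiencies are recomputed; the donor channel is left untouched
    because unbound frames carry the full donor signal, not background.

    ``fit`` is a no-op (the detector is stateless); ``transform``/``detect``
    convert trajectories to an :class:`EventSet`.
    """

    def __init__(self, threshold: float = 0.2, min_frames: int = 2,
                 subtract_background: bool = True):
        self.threshold = threshold
        self.min_frames = min_frames
        self.subtract_background = subtract_background

    def fit(self, X=None, y=None):
        if self.min_frames < 1:
            raise ValueError("min_frames must be at least 1")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")
        self.n_features_in_ = 0
        return self

    def detect(self, traj: FretTrajectory) -> EventSet:
        self.fit()
        if traj.n_frames < self.min_frames:
            raise ValueError("trajectory shorter than min_frames")
        I_A = traj.I_A
        e = fret_efficiency(traj.I_D, I_A)
        if self.subtract_background:
            unbound = ~(np.nan_to_num(e, nan=-1.0) >= self.threshold)
            if unbound.any():
                bg_a = float(np.median(I_A[unbound]))
                I_A = I_A - bg_a
                e = fret_efficiency(traj.I_D, I_A)
        bound = np.nan_to_num(e, nan=-1.0) >= self.threshold
        dt = traj.frame_dt
        events: list[BindingEvent] = []
        n = traj.n_frames
        for i0, i1 in _bound_runs(bound):
            if i1 - i0 < self.min_frames:
                continue
            frame_e = e[i0:i1]
            events.append(BindingEvent(
                traj_id=traj.traj_id,
                start_s=float(traj.times[i0]),
                end_s=float(traj.times[i0] + (i1 - i0) * dt),
                mean_E=float(np.mean(frame_e)),
                left_censored=(i0 == 0),
                right_censored=(i1 == n),
                frame_E=np.asarray(frame_e, dtype=float),
            ))
        meta = {traj.traj_id: {"frame_dt": dt, "duration": traj.duration,
                               "t0": float(traj.times[0])}}
        return EventSet(events=events, meta=meta)

    def transform(self, X) -> EventSet:
        """Detect events on a trajectory or an iterable of trajectories."""
        if isinstance(X, FretTrajectory):
            return self.detect(X)
        return EventSet.merge([self.detect(tr) for tr in X])


def detect_events(traj, threshold: float = 0.2, min_frames: int = 2,
                  subtract_background: bool = True) -> EventSet:
    """Functional wrapper over :class:`ThresholdEventDetector`."""
    det = ThresholdEventDetector(threshold=threshold, min_frames=min_frames,
                                 subtract_background=subtract_background)
    return det.transform(traj)


def dwell_times(es: EventSet, include_censored: bool = False) -> np.ndarray:
    """Bound dwell durations in seconds (censored events excluded by default)."""
    return np.array([e.dwell_s for e in es.events
                     if include_censored or not e.censored], dtype=float)


def rebind_times(es: EventSet) -> np.ndarray:
    """Gaps between consecutive events within each trajectory (seconds)."""
    gaps: list[float] = []
    for evs in es.by_trajectory().values():
        for a, b in zip(evs, evs[1:]):
            gaps.append(b.start_s - a.end_s)
    return np.array(gaps, dtype=float)


def efficiency_histogram(es: EventSet, bin_width: float = 0.05):
    """Histogram of per-frame efficiencies within bound events.

    Bins are centered on multiples of ``bin_width`` (the bin "0.70" covers
    [0.675, 0.725)).  Returns ``(centers, counts, mode)`` where ``mode`` is
    the center of the most populated bin.
    """
    if not es.events:
        raise ValueError("EventSet contains no events")
    if not (0 < bin_width <= 1):
        raise ValueError("bin_width must lie in (0, 1]")
    values = np.concatenate([np.asarray(e.frame_E, dtype=float) for e in es.events])
    n_bins = int(np.ceil(1.0 / bin_width)) + 1
    centers = np.round(np.arange(n_bins) * bin_width, 12)
    edges = np.concatenate(([centers[0] - bin_width / 2],
                            centers + bin_width / 2))
    counts, _ = np.histogram(values, bins=edges)
    mode = float(centers[int(np.argmax(counts))])
    return centers, counts, mode
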
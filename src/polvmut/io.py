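"""CSV readers and writers for the pipeline's exchange formats.

All files are comma-separated, UTF-8, LF line endings, ``.`` decimal:

* time courses: ``time_min, pe_fraction[, replicate_id]``
* activity series: ``time_min, rel_activity``
* trajectories: ``traj_id, frame, time_s, intensity_donor, intensity_acceptor``
* events: ``traj_id, start_s, end_s, dwell_s, mean_E, left_censored, right_censored``
* ground-truth events: ``traj_id, start_s, end_s, state``
* ensemble traces: ``time_min, frac_s1, frac_s2, frac_s3, pe``
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .deactivation import ActivitySeries, TimeCourse
from .events import BindingEvent, EventSet, FretTrajectory

__all__ = [
    "read_timecourse", "write_timecourse",
    "read_activity", "write_activity",
    "read_trajectories", "write_trajectories",
    "read_events", "write_events",
    "write_true_events", "write_trace",
]

_CSV_KW = dict(index=False, lineterminator="\n")


def write_timecourse(path, tc: TimeCourse) -> None:
    cols = {"time_min": tc.times, "pe_fraction": tc.pe}
    if tc.pe_sd is not None:
        cols["pe_sd"] = tc.pe_sd
    pd.DataFrame(cols).to_csv(path, **_CSV_KW)


def read_timecourse(path) -> TimeCourse:
    df = pd.read_csv(path)
    if "replicate_id" in df.columns:
        g = df.groupby("time_min", sort=True)["pe_fraction"]
        times = np.array(sorted(df["time_min"].unique()), dtype=float)
        pe = g.mean().to_numpy()
        n_rep = df["replicate_id"].nunique()
        sd = g.std(ddof=1).to_numpy() if n_rep >= 2 else None
        return TimeCourse(times=times, pe=pe, pe_sd=sd)
    sd = df["pe_sd"].to_numpy() if "pe_sd" in df.columns else None
    return TimeCourse(times=df["time_min"].to_numpy(),
                      pe=df["pe_fraction"].to_numpy(), pe_sd=sd)


def write_activity(path, series: ActivitySeries) -> None:
    pd.DataFrame({"time_min": series.times,
                  "rel_activity": series.rel_activity}).to_csv(path, **_CSV_KW)


def read_activity(path) -> ActivitySeries:
    df = pd.read_csv(path)
    return ActivitySeries(times=df["time_min"].to_numpy(),
                          rel_activity=df["rel_activity"].to_numpy())


def write_trajectories(path, trajs: list[FretTrajectory]) -> None:
    frames = []
    for tr in trajs:
        frames.append(pd.DataFrame({
            "traj_id": tr.traj_id,
            "frame": np.arange(tr.n_frames),
            "time_s": tr.times,
            "intensity_donor": tr.I_D,
            "intensity_acceptor": tr.I_A,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, **_CSV_KW)


def read_trajectories(path) -> list[FretTrajectory]:
    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("traj_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(FretTrajectory(str(tid), grp["time_s"].to_numpy(),
                                  grp["intensity_donor"].to_numpy(),
                                  grp["intensity_acceptor"].to_numpy()))
    return out


def write_events(path, es: EventSet) -> None:
    pd.DataFrame({
        "traj_id": [e.traj_id for e in es.events],
        "start_s": [e.start_s for e in es.events],
        "end_s": [e.end_s for e in es.events],
        "dwell_s": [e.dwell_s for e in es.events],
        "mean_E": [e.mean_E for e in es.events],
        "left_censored": [e.left_censored for e in es.events],
        "right_censored": [e.right_censored for e in es.events],
    }).to_csv(path, **_CSV_KW)


def read_events(path) -> EventSet:
    df = pd.read_csv(path)
    events = [
        BindingEvent(
            traj_id=str(r.traj_id), start_s=float(r.start_s), end_s=float(r.end_s),
            mean_E=float(r.mean_E), left_censored=bool(r.left_censored),
            right_censored=bool(r.right_censored),
            frame_E=np.array([float(r.mean_E)]),
        )
        for r in df.itertuples()
    ]
    return EventSet(events=events, meta={})


def write_true_events(path, truth) -> None:
    from .synthetic import true_events_frame
    true_events_frame(truth).to_csv(path, **_CSV_KW)


def write_trace(path, trace) -> None:
    trace.to_frame().to_csv(path, **_CSV_KW)
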
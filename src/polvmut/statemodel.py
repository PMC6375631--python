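"""Stochastic three-state conformational switch of pol V Mut.

State 1: assembled but catalytically inactive (no nucleotide cofactor bound;
cannot bind DNA).  State 2: activated by ATP/ATPgammaS binding — the only
state in which DNA binding and synthesis occur.  State 3: deactivated; inert
until a fresh RecA* dose restores it to state 2.

Each molecule is simulated as a continuous-time Markov process with exact
exponential event-time sampling (1 -> 2 at ``k_act``, 2 -> 3 at the dynamic
rate while synthesizing or the static rate otherwise); reactivation is an
instantaneous Bernoulli restoration (probability ``reactivation_eff``) of
state-3 molecules at each dosing time.  The ensemble's predicted extension is
``pe(t) = 1 - exp(-k_syn * <A(t)>)`` where ``<A(t)>`` is the mean per-molecule
time spent in state 2 up to ``t`` — the ensemble-level integral of the active
fraction, which converges to the closed-form deactivation model
as the ensemble grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deactivation import model_pe  # noqa: F401  (re-exported oracle counterpart)

__all__ = ["StateModelParams", "EnsembleTrace", "simulate_ensemble",
           "reactivation_response"]


@dataclass(frozen=True)
class StateModelParams:
    """Rates (min^-1) and ensemble settings for the three-state switch.

    ``k_act = inf`` (the default) makes ATP activation effectively
    instantaneous, so molecules start in state 2.  ``synthesizing`` selects
    which deactivation rate applies to state 2: the dynamic rate ``D_dyn``
    during synthesis or the static rate ``D_stat`` when synthesis is disabled.
    """

    k_syn: float = 0.008
    D_dyn: float = 0.028
    D_stat: float = 0.015
    k_act: float = np.inf
    synthesizing: bool = True
    reactivation_times: tuple[float, ...] = ()
    reactivation_eff: float = 1.0
    n_molecules: int = 10_000
    seed: int = 0

    def __post_init__(self):
        for name in ("k_syn", "D_dyn", "D_stat", "k_act"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.reactivation_eff <= 1.0):
            raise ValueError("reactivation_eff must lie in [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be at least 1")
        rt = tuple(sorted(float(r) for r in self.reactivation_times))
        if any(r <= 0 for r in rt):
            raise ValueError("reactivation times must be positive")
        object.__setattr__(self, "reactivation_times", rt)

    @property
    def deactivation_rate(self) -> float:
        return self.D_dyn if self.synthesizing else self.D_stat


@dataclass(frozen=True)
class EnsembleTrace:
    """Ensemble occupancies and predicted extension on a reporting grid."""

    times: np.ndarray
    frac_state1: np.ndarray
    frac_state2: np.ndarray
    frac_state3: np.ndarray
    predicted_pe: np.ndarray

    def __post_init__(self):
        total = self.frac_state1 + self.frac_state2 + self.frac_state3
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("state occupancies must sum to 1 at every time")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_min": self.times,
            "frac_s1": self.frac_state1,
            "frac_s2": self.frac_state2,
            "frac_s3": self.frac_state3,
            "pe": self.predicted_pe,
        })


def _simulate_molecule(rng: np.random.Generator, params: StateModelParams,
                       t_end: float):
    """One molecule's path: (transition times, states after each transition,
    state-2 intervals)."""
    d_rate = params.deactivation_rate
    k_act = params.k_act
    eff = params.reactivation_eff
    doses = [r for r in params.reactivation_times if r < t_end]

    t = 0.0
    state = 2 if np.isinf(k_act) else 1
    enter2 = 0.0 if state == 2 else None
    trans_t: list[float] = []
    trans_s: list[int] = []
    intervals: list[tuple[float, float]] = []
    di = 0  # next dose index

    # Each dwell is drawn once (memoryless, so doses passing over states 1/2
    # need no redraw); a dose only matters to a molecule sitting in state 3,
    # and the Bernoulli restoration draws no random number at eff 0 or 1.
    while t < t_end:
        if state == 1:
            if k_act == 0:
                break
            t_next = t + float(rng.exponential(1.0 / k_act))
            if t_next >= t_end:
                break
            t = t_next
            state = 2
            enter2 = t
            trans_t.append(t)
            trans_s.append(2)
        elif state == 2:
            t_next = t + float(rng.exponential(1.0 / d_rate)) if d_rate > 0 else np.inf
            if t_next >= t_end:
                break
            t = t_next
            intervals.append((enter2, t))
            enter2 = None
            state = 3
            trans_t.append(t)
            trans_s.append(3)
        else:  # state 3: inert until the next RecA* dose
            while di < len(doses) and doses[di] <= t:
                di += 1
            if di >= len(doses):
                break
            t = doses[di]
            di += 1
            restored = eff >= 1.0 or (eff > 0.0 and rng.random() < eff)
            if restored:
                state = 2
                enter2 = t
                trans_t.append(t)
                trans_s.append(2)
    if state == 2:
        intervals.append((enter2, t_end))
    return trans_t, trans_s, intervals


def simulate_ensemble(params: StateModelParams, t_grid) -> EnsembleTrace:
    """Simulate the ensemble and report occupancies and predicted extension.

    ``t_grid`` is a strictly increasing grid of reporting times in minutes;
    event times are sampled exactly, the grid is for reporting only.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid must not be empty")
    if np.any(np.diff(t_grid) <= 0) or np.any(t_grid < 0):
        raise ValueError("t_grid must be nonnegative and strictly increasing")
    t_end = float(t_grid[-1])
    rng = np.random.default_rng(params.seed)
    n = params.n_molecules

    counts = np.zeros((3, t_grid.size), dtype=np.int64)
    active_integral = np.zeros(t_grid.size, dtype=float)
    init_state = 2 if np.isinf(params.k_act) else 1

    for _ in range(n):
        trans_t, trans_s, intervals = _simulate_molecule(rng, params, t_end)
        # state occupancy at each grid time
        if trans_t:
            idx = np.searchsorted(trans_t, t_grid, side="right")
            states = np.array([init_state] + trans_s, dtype=np.int64)[idx]
        else:
            states = np.full(t_grid.size, init_state, dtype=np.int64)
        for s in (1, 2, 3):
            counts[s - 1] += states == s
        # accumulated time in state 2 up to each grid point
        for a, b in intervals:
            active_integral += np.clip(t_grid - a, 0.0, b - a)

    frac = counts / n
    mean_active = active_integral / n
    pe = -np.expm1(-params.k_syn * mean_active)
    return EnsembleTrace(times=t_grid, frac_state1=frac[0], frac_state2=frac[1],
                         frac_state3=frac[2], predicted_pe=pe)


def reactivation_response(params: StateModelParams, t_grid) -> EnsembleTrace:
    """Ensemble response to RecA* dosing.

    Requires every reactivation time to lie inside the reporting grid; the
    simulation itself is :func:`simulate_ensemble`.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if not params.reactivation_times:
        raise ValueError("params carry no reactivation times")
    for r in params.reactivation_times:
        if not (t_grid[0] < r < t_grid[-1]):
            raise ValueError(f"reactivation time {r} lies outside the grid")
    return simulate_ensemble(params, t_grid)
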
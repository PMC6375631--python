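"""Dynamic and static deactivation kinetics of pol V Mut.

Primer-extension time courses are modelled with two parameters: an intrinsic
(pseudo-first-order) synthesis rate constant ``k`` and a deactivation rate
``D``, both in min^-1.  Extension follows first-order kinetics
``dP/dt = k'(t) (1 - P)`` while deactivation depletes the active enzyme pool
as a Poisson process, ``k'(t) = k exp(-D t)``.  Integration gives

    P(t) = 1 - exp(-(k/D) (1 - e^{-D t}))

which satisfies the short-time limit ``ln(1 - P) ~ -k t`` and plateaus at
``P(inf) = 1 - e^{-k/D}``.  A historical variant of the integrated equation,
``ln(1 - P) = -k t + k (e^{-D t} - D t - 1)/D``, is retained behind the
``as_printed`` flag for comparison; it does not satisfy the short-time limit
(it reduces to ``-3 k t``) and is not used for fitting by default.

Static deactivation (loss of activity during incubation without synthesis) is
treated as simple exponential decay of relative activity, and two-temperature
Arrhenius analysis converts a pair of decay rates into an activation energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TimeCourse",
    "ActivitySeries",
    "DynamicFit",
    "ArrheniusResult",
    "FitConvergenceError",
    "model_pe",
    "fit_initial_rate",
    "fit_deactivation",
    "percent_extended",
    "static_rate",
    "arrhenius_ea",
    "predict_rounds",
    "DynamicDeactivationModel",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

_KELVIN_OFFSET = 273.15


class FitConvergenceError(RuntimeError):
    """Raised when a nonlinear fit fails to converge."""


@dataclass(frozen=True)
class TimeCourse:
    """A primer-extension time course.

    Parameters
    ----------
    times : array-like
        Sample times in minutes, strictly increasing.
    pe : array-like
        Fraction of primer extended at each time (mean over replicates),
        each in [0, 1].
    pe_sd : array-like, optional
        Per-time replicate standard deviation of the extended fraction.
    """

    times: np.ndarray
    pe: np.ndarray
    pe_sd: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.pe, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pe", p)
        if t.ndim != 1 or p.shape != t.shape:
            raise ValueError("times and pe must be 1-d arrays of equal length")
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValueError(f"times must be strictly increasing; offending index {bad[0] + 1}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("pe values must lie in [0, 1]")
        if self.pe_sd is not None:
            sd = np.asarray(self.pe_sd, dtype=float)
            if sd.shape != t.shape or np.any(sd < 0):
                raise ValueError("pe_sd must be nonnegative and match times in length")
            object.__setattr__(self, "pe_sd", sd)


@dataclass(frozen=True)
class ActivitySeries:
    """Relative polymerase activity vs incubation time (minutes).

    ``rel_activity`` is the activity at each time divided by the activity at
    t = 0, so the noiseless series starts at 1.
    """

    times: np.ndarray
    rel_activity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.rel_activity, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "rel_activity", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("times and rel_activity must be 1-d arrays of equal length")
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValueError(f"times must be strictly increasing; offending index {bad[0] + 1}")
        if np.any(a < 0):
            raise ValueError("rel_activity must be nonnegative")


@dataclass(frozen=True)
class DynamicFit:
    """Result of the two-parameter dynamic-deactivation fit."""

    k: float
    D: float
    k_se: float
    D_se: float
    window_n: int
    residual_rms: float
    converged: bool = True

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "D": self.D,
            "k_se": self.k_se,
            "D_se": self.D_se,
            "window_n": self.window_n,
            "residual_rms": self.residual_rms,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class ArrheniusResult:
    """Two-point Arrhenius analysis of deactivation rates."""

    ea: float  # kcal/mol
    rate_low_T: float
    rate_high_T: float
    T_low: float  # Kelvin
    T_high: float  # Kelvin


def model_pe(t, k: float, D: float, as_printed: bool = False):
    """Fraction of primer extended at time ``t`` (minutes).

    Evaluates ``P(t) = 1 - exp(-(k/D)(1 - e^{-D t}))``; for ``D == 0`` the
    no-deactivation limit ``1 - e^{-k t}`` is returned.  ``as_printed``
    selects the historical integrated form (requires ``D > 0``).
    """
    t = np.asarray(t, dtype=float)
    if k < 0 or D < 0:
        raise ValueError("rate constants k and D must be nonnegative")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if as_printed:
        if D == 0:
            raise ValueError("the as-printed integrated form is undefined at D = 0")
        log1m = -k * t + k * (np.exp(-D * t) - D * t - 1.0) / D
        out = -np.expm1(log1m)
    else:
        # (k/D)(1 - e^{-Dt}) = k t * (1 - e^{-x})/x with x = D t, evaluated
        # stably through the small-x limit (x -> 0 gives the D = 0 form).
        x = D * t
        small = x < 1e-8
        safe = np.where(small, 1.0, x)
        ratio = np.where(small, 1.0 - x / 2.0, -np.expm1(-safe) / safe)
        out = -np.expm1(-k * t * ratio)
    return float(out) if out.ndim == 0 else out


def percent_extended(unextended, extended) -> float:
    """Fraction extended from per-lane band intensities.

    ``sum(extended) / (unextended + sum(extended))`` — extended-band
    intensity over total lane intensity.
    """
    ext = np.atleast_1d(np.asarray(extended, dtype=float))
    un = float(unextended)
    if un < 0 or np.any(ext < 0):
        raise ValueError("band intensities must be nonnegative")
    total = un + ext.sum()
    if total <= 0:
        raise ValueError("total band intensity must be positive (all-zero lane)")
    return float(ext.sum() / total)


def fit_initial_rate(tc: TimeCourse, window_n: int = 3, pe_max: float = 0.1) -> float:
    """Initial-rate estimate of the synthesis rate constant ``k``.

    Least-squares slope (through the origin, since P(0) = 0) of
    ``-ln(1 - pe)`` versus time over the first ``window_n`` usable points.
    Points with ``pe == 1`` are dropped with a warning; points are taken from
    the early low-extension regime (``pe < pe_max``) when at least two such
    points exist, otherwise from the start of the series.
    """
    if window_n < 2:
        raise ValueError("window_n must be at least 2")
    t, p = tc.times, tc.pe
    sat = p >= 1.0
    if np.any(sat):
        warnings.warn(
            f"dropping {int(sat.sum())} fully-extended point(s) from initial-rate window",
            stacklevel=2,
        )
    usable = ~sat
    early = usable & (p < pe_max)
    pool = early if early.sum() >= 2 else usable
    idx = np.flatnonzero(pool)[:window_n]
    if idx.size < 2:
        raise ValueError("fewer than 2 usable points for the initial-rate fit")
    ti, yi = t[idx], -np.log1p(-p[idx])
    denom = np.dot(ti, ti)
    if denom == 0:
        raise ValueError("initial-rate window contains no nonzero times")
    return float(np.dot(ti, yi) / denom)


class DynamicDeactivationModel(RegressorMixin, BaseEstimator):
    """Two-parameter (k, D) dynamic-deactivation curve model.

    sklearn-style estimator: ``fit(t, pe)`` performs nonlinear least squares
    of the closed-form extension model over the full profile, seeding ``k``
    from the initial-rate slope.  Inverse-variance weighting is applied when
    per-point standard deviations are supplied.

    Parameters
    ----------
    window_n : int
        Number of early points used for the initial-rate seed of ``k``.
    pe_max : float
        Upper extension bound defining the "early" initial-rate regime.
    as_printed : bool
        Fit the historical integrated equation instead of the corrected form.

    Attributes
    ----------
    k_, D_ : float
        Fitted synthesis and deactivation rate constants (min^-1).
    k_se_, D_se_ : float
        Standard errors from the fit covariance.
    residual_rms_ : float
        Root-mean-square residual on the fraction-extended scale.
    converged_ : bool
        True when the optimizer converged (always true on a fitted model;
        non-convergence raises :class:`FitConvergenceError`).
    """

    def __init__(self, window_n: int = 3, pe_max: float = 0.1, as_printed: bool = False):
        self.window_n = window_n
        self.pe_max = pe_max
        self.as_printed = as_printed

    def fit(self, t, pe, pe_sd=None):
        tc = TimeCourse(np.asarray(t, float), np.asarray(pe, float),
                        None if pe_sd is None else np.asarray(pe_sd, float))
        if tc.times.size < 4:
            raise ValueError("at least 4 time points are required for the two-parameter fit")
        try:
            k0 = fit_initial_rate(tc, window_n=self.window_n, pe_max=self.pe_max)
        except ValueError:
            k0 = 0.01
        k0 = max(k0, 1e-6)
        # Seed D from the apparent plateau when one is visible.
        p_max = float(np.clip(tc.pe.max(), 1e-6, 1 - 1e-9))
        d0 = max(k0 / max(-np.log1p(-p_max), 1e-9), 1e-4)

        sigma = None
        if tc.pe_sd is not None and np.all(tc.pe_sd > 0):
            sigma = tc.pe_sd

        def f(tt, k, D):
            return model_pe(tt, k, D, as_printed=self.as_printed)

        lower_d = 1e-12 if self.as_printed else 0.0
        last_err: Exception | None = None
        for p0 in ([k0, d0], [k0, 1e-3], [k0, 0.1]):
            try:
                popt, pcov = curve_fit(
                    f, tc.times, tc.pe, p0=p0, sigma=sigma,
                    bounds=([0.0, lower_d], [np.inf, np.inf]), maxfev=20000,
                )
                break
            except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
                last_err = err
        else:  # pragma: no cover
            raise FitConvergenceError(f"dynamic-deactivation fit did not converge: {last_err}")

        self.k_, self.D_ = float(popt[0]), float(popt[1])
        ses = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        self.k_se_, self.D_se_ = float(ses[0]), float(ses[1])
        resid = tc.pe - f(tc.times, *popt)
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        self.window_n_ = self.window_n
        self.converged_ = True
        return self

    def predict(self, t):
        return model_pe(np.asarray(t, float), self.k_, self.D_, as_printed=self.as_printed)

    def result_(self) -> DynamicFit:
        return DynamicFit(
            k=self.k_, D=self.D_, k_se=self.k_se_, D_se=self.D_se_,
            window_n=self.window_n_, residual_rms=self.residual_rms_,
            converged=self.converged_,
        )


def fit_deactivation(tc: TimeCourse, k_init: float | None = None,
                     D_init: float | None = None, window_n: int = 3,
                     as_printed: bool = False) -> DynamicFit:
    """Fit the two-parameter deactivation model to a time course.

    Thin wrapper over :class:`DynamicDeactivationModel`; ``k_init``/``D_init``
    are accepted for interface completeness but the estimator re-derives its
    own seeds from the data (the initial-rate slope), which is more robust.
    """
    est = DynamicDeactivationModel(window_n=window_n, as_printed=as_printed)
    est.fit(tc.times, tc.pe, pe_sd=tc.pe_sd)
    return est.result_()


def static_rate(series: ActivitySeries, t_ref: float = 30.0,
                convention: str = "exponential") -> float:
    """Initial static deactivation rate from the activity drop at ``t_ref``.

    Under the exponential-decay convention the rate is ``-ln(A(t_ref))/t_ref``;
    ``convention="linear"`` gives ``(1 - A(t_ref))/t_ref`` instead.  The
    relative activity at ``t_ref`` is linearly interpolated when ``t_ref`` is
    not a sample time.
    """
    if t_ref <= 0:
        raise ValueError("t_ref must be positive")
    t, a = series.times, series.rel_activity
    if t_ref < t[0] or t_ref > t[-1]:
        raise ValueError("t_ref lies outside the measured time range")
    a_ref = float(np.interp(t_ref, t, a))
    if a_ref <= 0:
        raise ValueError("relative activity at t_ref must be positive")
    if convention == "exponential":
        return float(-np.log(a_ref) / t_ref)
    if convention == "linear":
        return float((1.0 - a_ref) / t_ref)
    raise ValueError(f"unknown convention {convention!r}")


def arrhenius_ea(rate_low: float, T_low_C: float, rate_high: float,
                 T_high_C: float) -> ArrheniusResult:
    """Two-point Arrhenius activation energy (kcal/mol).

    ``Ea = R ln(rate_high/rate_low) / (1/T_low - 1/T_high)`` with temperatures
    in Kelvin (``K = degC + 273.15``) and R = 1.9872e-3 kcal mol^-1 K^-1.
    ``rate_low``/``rate_high`` are the decay rates at the lower and higher
    temperature respectively.
    """
    if rate_low <= 0 or rate_high <= 0:
        raise ValueError("rates must be positive")
    T_low = T_low_C + _KELVIN_OFFSET
    T_high = T_high_C + _KELVIN_OFFSET
    if T_low <= 0 or T_high <= 0:
        raise ValueError("temperatures must exceed absolute zero")
    if T_high == T_low:
        raise ValueError("temperatures must be distinct")
    if T_high < T_low:
        raise ValueError("T_high must exceed T_low")
    ea = R_KCAL * np.log(rate_high / rate_low) / (1.0 / T_low - 1.0 / T_high)
    return ArrheniusResult(ea=float(ea), rate_low_T=rate_low, rate_high_T=rate_high,
                           T_low=T_low, T_high=T_high)


def predict_rounds(k: float, D: float, dna_excess: float) -> float:
    """Rounds of DNA synthesis before deactivation halts extension.

    The plateau extension fraction ``1 - e^{-k/D}`` divided by the per-round
    fraction ``1/dna_excess``.  With no deactivation (D = 0) the plateau is 1
    and the enzyme completes all ``dna_excess`` rounds.
    """
    if dna_excess < 1:
        raise ValueError("dna_excess must be at least 1")
    if k < 0 or D < 0:
        raise ValueError("rate constants must be nonnegative")
    if k == 0:
        return 0.0
    plateau = 1.0 if D == 0 else float(-np.expm1(-k / D))
    return plateau * dna_excess
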
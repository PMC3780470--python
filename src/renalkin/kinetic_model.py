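"""Parallel two-tissue compartment model for renal PET radioligand kinetics.

The kidney lacks a blood-tissue barrier, so specific (receptor) and
nonspecific binding sites both exchange directly with arterial blood and
the two tissue compartments are connected in parallel:

    dC_NS/dt = K1*C_A(t) - k2*C_NS(t)
    dC_S/dt  = K3*C_A(t) - k4*C_S(t)

The tissue impulse response is therefore a plain biexponential,
f(t) = K1*exp(-k2*t) + K3*exp(-k4*t), and the measured PET signal is

    PET(t) = BV*C_A(t) + (1 - BV) * (C_A (*) f)(t)

with BV the fractional blood volume. Distribution volumes follow as
DV_NS = K1/k2, DV_S = K3/k4, DV_T = DV_NS + DV_S and the binding ratio
DVR = DV_S/DV_NS. Time is in minutes throughout; K1, K3 in mL/min/mL;
k2, k4 in 1/min; activities in Bq/mL/MBq (decay-corrected and
dose-normalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "InputFunction",
    "RateConstants",
    "ImpulseResponse",
    "BindingParameters",
    "impulse_response",
    "solve_compartments",
    "model_tac",
    "distribution_volumes",
    "retention_from_tac",
    "retention_from_irf",
]

_CONTIG_TOL = 1e-9


@dataclass(frozen=True)
class FrameSchedule:
    """Non-uniform dynamic acquisition timing, minutes.

    Frames must be contiguous, non-overlapping and start at t = 0.
    """

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.start_times, dtype=float)
        durs = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "start_times", starts)
        object.__setattr__(self, "durations", durs)
        if starts.ndim != 1 or starts.shape != durs.shape or starts.size == 0:
            raise ValueError("start_times and durations must be equal-length 1-d arrays")
        if abs(starts[0]) > _CONTIG_TOL:
            raise ValueError("first frame must start at t=0")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame start times must be strictly increasing")
        # 5e-4 min = 30 ms: far below any frame duration, tolerant of
        # round-tripping through fixed-precision text formats
        gaps = starts[1:] - (starts[:-1] + durs[:-1])
        if np.any(np.abs(gaps) > 5e-4):
            i = int(np.argmax(np.abs(gaps)))
            raise ValueError(
                f"frames must be contiguous: frame {i} ends at "
                f"{starts[i] + durs[i]:g} but frame {i + 1} starts at {starts[i + 1]:g}"
            )

    @property
    def mid_times(self) -> np.ndarray:
        return self.start_times + self.durations / 2.0

    @property
    def end_time(self) -> float:
        return float(self.start_times[-1] + self.durations[-1])

    def __len__(self) -> int:
        return self.start_times.size

    @classmethod
    def from_durations(cls, durations) -> "FrameSchedule":
        durs = np.asarray(durations, dtype=float)
        starts = np.concatenate(([0.0], np.cumsum(durs)[:-1]))
        return cls(starts, durs)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Decay-corrected, dose-normalized regional activity per frame (Bq/mL/MBq)."""

    schedule: FrameSchedule
    activity: np.ndarray
    label: str = ""

    def __post_init__(self):
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        if act.shape != (len(self.schedule),):
            raise ValueError("activity length must equal frame count")
        if not np.all(np.isfinite(act)):
            raise ValueError("activity values must be finite")
        if np.any(act < 0):
            raise ValueError("activity values must be nonnegative")


@dataclass(frozen=True)
class InputFunction:
    """Metabolite-corrected arterial plasma concentration C_A(t).

    The measured whole-blood term of the measurement equation is treated as
    identical to this curve (only one arterial curve is available).
    """

    times: np.ndarray
    activity: np.ndarray
    interpolation: str = "linear"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "activity", a)
        if t.ndim != 1 or t.shape != a.shape or t.size < 2:
            raise ValueError("times and activity must be equal-length 1-d arrays (n >= 2)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] < -_CONTIG_TOL:
            raise ValueError("times must start at or after 0")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("activity must be finite and nonnegative")
        if self.interpolation != "linear":
            raise ValueError(f"unknown interpolation rule {self.interpolation!r}")

    @property
    def end_time(self) -> float:
        return float(self.times[-1])

    def __call__(self, t) -> np.ndarray:
        """Linear interpolation; zero before the first sample."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.activity,
                         left=0.0, right=float(self.activity[-1]))


@dataclass(frozen=True)
class RateConstants:
    """Rate constants of the parallel model.

    K1/k2 govern the fast nonspecific component, K3/k4 the slow specific
    (receptor) component; the labelling convention is k2 > k4.
    """

    K1: float
    k2: float
    K3: float
    k4: float

    def __post_init__(self):
        for name in ("K1", "k2", "K3", "k4"):
            v = float(getattr(self, name))
            object.__setattr__(self, name, v)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")

    def relabeled(self) -> "RateConstants":
        """Swap components so that the fast washout constant is labelled k2."""
        if self.k2 >= self.k4:
            return self
        return RateConstants(self.K3, self.k4, self.K1, self.k2)

    def as_tuple(self) -> tuple:
        return (self.K1, self.k2, self.K3, self.k4)


@dataclass(frozen=True)
class ImpulseResponse:
    """Tissue response to an instantaneous unit arterial input (mL/min/mL).

    Either analytic (holds the rate constants of the biexponential) or a
    sampled estimate on a uniform grid, e.g. from deconvolution.
    """

    rc: RateConstants | None = None
    times: np.ndarray | None = None
    values: np.ndarray | None = None

    def __post_init__(self):
        if (self.rc is None) == (self.values is None):
            raise ValueError("provide either rate constants or sampled values")
        if self.values is not None:
            t = np.asarray(self.times, dtype=float)
            v = np.asarray(self.values, dtype=float)
            object.__setattr__(self, "times", t)
            object.__setattr__(self, "values", v)
            if t.shape != v.shape or t.ndim != 1 or t.size < 2:
                raise ValueError("sampled IRF needs matching 1-d times and values")
            if not np.all(np.isfinite(v)):
                raise ValueError("sampled IRF values must be finite")

    @property
    def is_analytic(self) -> bool:
        return self.rc is not None

    def __call__(self, t) -> np.ndarray:
        if self.is_analytic:
            return impulse_response(self.rc, t)
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)


@dataclass(frozen=True)
class BindingParameters:
    """Distribution volumes and retention measures of radioligand binding.

    DV_NS, DV_S, DV_T are unitless distribution volumes (mL/mL); DVR is the
    specific-to-nonspecific ratio. y_ret is the tissue-curve retention
    (80-min value over maximum) and f_ret the analogous impulse-response
    retention; either may be NaN when the quantity is not available.
    """

    dv_ns: float
    dv_s: float
    dvr: float
    y_ret: float = float("nan")
    f_ret: float = float("nan")

    @property
    def dv_t(self) -> float:
        return self.dv_ns + self.dv_s


def impulse_response(rc: RateConstants, t) -> np.ndarray:
    """Biexponential impulse response K1*exp(-k2*t) + K3*exp(-k4*t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("impulse response is defined for t >= 0 only")
    return rc.K1 * np.exp(-rc.k2 * t) + rc.K3 * np.exp(-rc.k4 * t)


def _check_uniform(t_grid: np.ndarray) -> float:
    steps = np.diff(t_grid)
    if t_grid.size < 2 or np.any(steps <= 0):
        raise ValueError("time grid must be increasing with at least 2 points")
    dt = float(steps[0])
    if np.any(np.abs(steps - dt) > 1e-9 * max(dt, 1.0)):
        raise ValueError("time grid must be uniform")
    return dt


def _exp_convolve(K: float, k: float, x: np.ndarray, dt: float) -> np.ndarray:
    """K * int_0^t x(tau) exp(-k (t - tau)) dtau on a uniform grid.

    Exact for piecewise-linear x: the update from one grid point to the
    next is a constant-coefficient first-order recursion, evaluated with
    an IIR filter.  C(0) = 0 by definition; the filter's spurious response
    to x[0] decays homogeneously and is subtracted.
    """
    ekh = np.exp(-k * dt)
    i1 = (1.0 - ekh) / k
    i2 = 1.0 / k - i1 / (k * dt)
    b = np.array([K * i2, K * (i1 - i2)])
    a = np.array([1.0, -ekh])
    y = lfilter(b, a, x)
    if x[0] != 0.0:
        n = np.arange(x.size)
        y = y - b[0] * x[0] * ekh**n
        y[0] = 0.0
    return y


def _exp_convolve_at(K: float, k: float, x: np.ndarray, dt: float,
                     c_grid: np.ndarray, t_query: np.ndarray,
                     x_query: np.ndarray) -> np.ndarray:
    """Evaluate the convolution exactly at off-grid times.

    Propagates the grid solution from the nearest lower grid point across
    the fractional step, again exactly for piecewise-linear x.
    """
    t_query = np.asarray(t_query, dtype=float)
    idx = np.minimum(np.floor(t_query / dt + 1e-12).astype(int), c_grid.size - 1)
    delta = np.maximum(t_query - idx * dt, 0.0)
    small = delta < 1e-12
    d = np.where(small, 1.0, delta)
    ekd = np.exp(-k * d)
    i1 = (1.0 - ekd) / k
    i2 = 1.0 / k - i1 / (k * d)
    step = K * ((i1 - i2) * x[idx] + i2 * x_query)
    out = c_grid[idx] * np.exp(-k * delta) + np.where(small, 0.0, step)
    return out


def solve_compartments(rc: RateConstants, input_fn: InputFunction, t_grid):
    """Integrate the compartment ODEs on a uniform grid.

    Returns (C_NS, C_S).  The integrator is exact for the piecewise-linear
    interpolant of the input, so accuracy is limited only by the grid
    resolution of the input curve itself.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    dt = _check_uniform(t_grid)
    if t_grid[0] < -_CONTIG_TOL:
        raise ValueError("grid must start at t >= 0")
    x = input_fn(t_grid)
    c_ns = _exp_convolve(rc.K1, rc.k2, x, dt)
    c_s = _exp_convolve(rc.K3, rc.k4, x, dt)
    return c_ns, c_s


def model_tac(
    rc: RateConstants,
    input_fn: InputFunction,
    bv: float,
    schedule: FrameSchedule,
    sampling: str = "midpoint",
    dt: float = 0.01,
) -> TimeActivityCurve:
    """Forward-model a regional TAC from the measurement equation.

    PET(t) = bv*C_A(t) + (1-bv)*(C_A (*) f)(t), evaluated on a fine uniform
    grid and sampled per frame either at the frame mid-time (default,
    matching mid-scan reporting) or as the frame average.
    """
    if not 0.0 <= bv < 1.0:
        raise ValueError(f"blood volume fraction must be in [0, 1), got {bv}")
    if sampling not in ("midpoint", "average"):
        raise ValueError(f"unknown sampling rule {sampling!r}")
    t_end = schedule.end_time
    n = int(np.ceil(t_end / dt)) + 1
    grid = np.linspace(0.0, t_end, n)
    dt_eff = grid[1] - grid[0]
    x = input_fn(grid)
    c_ns = _exp_convolve(rc.K1, rc.k2, x, dt_eff)
    c_s = _exp_convolve(rc.K3, rc.k4, x, dt_eff)
    if sampling == "midpoint":
        mids = schedule.mid_times
        x_mid = input_fn(mids)
        tissue = (_exp_convolve_at(rc.K1, rc.k2, x, dt_eff, c_ns, mids, x_mid)
                  + _exp_convolve_at(rc.K3, rc.k4, x, dt_eff, c_s, mids, x_mid))
        vals = bv * x_mid + (1.0 - bv) * tissue
    else:
        pet = bv * x + (1.0 - bv) * (c_ns + c_s)
        cum = np.concatenate(([0.0], np.cumsum((pet[1:] + pet[:-1]) / 2.0 * dt_eff)))
        lo = np.interp(schedule.start_times, grid, cum)
        hi = np.interp(schedule.start_times + schedule.durations, grid, cum)
        vals = (hi - lo) / schedule.durations
    return TimeActivityCurve(schedule, np.maximum(vals, 0.0), label="model")


def distribution_volumes(rc: RateConstants) -> BindingParameters:
    """Distribution volumes DV_NS = K1/k2, DV_S = K3/k4 and DVR = DV_S/DV_NS."""
    if np.isclose(rc.k2, rc.k4, rtol=1e-9, atol=0.0):
        raise ValueError(
            "k2 == k4: fast and slow components are unidentifiable, DVR undefined"
        )
    dv_ns = rc.K1 / rc.k2
    dv_s = rc.K3 / rc.k4
    return BindingParameters(dv_ns=dv_ns, dv_s=dv_s, dvr=dv_s / dv_ns)


def retention_from_tac(tac: TimeActivityCurve, t_ret: float = 80.0) -> float:
    """Tissue retention Y_ret: TAC value at t_ret over the TAC maximum.

    The value at t_ret is linearly interpolated between adjacent frame
    mid-times; t_ret must not exceed the last frame mid-time.
    """
    mids = tac.schedule.mid_times
    if t_ret > mids[-1] + _CONTIG_TOL:
        raise ValueError(
            f"retention time {t_ret:g} min beyond last frame mid-time {mids[-1]:g} min"
        )
    peak = float(np.max(tac.activity))
    if peak <= 0:
        raise ValueError("retention undefined for an all-zero curve")
    return float(np.interp(t_ret, mids, tac.activity)) / peak


def retention_from_irf(
    irf: ImpulseResponse,
    t_ret: float = 80.0,
    search_window: tuple | None = None,
) -> float:
    """Impulse-response retention f_ret: f(t_ret) over the maximum of f.

    For an analytic IRF the maximum is f(0) = K1 + K3.  For a sampled IRF
    the maximum is taken over the samples, optionally restricted to
    ``search_window`` (regularized deconvolution can displace or distort
    the early-time estimate, so fits typically search within the fitting
    window).
    """
    if t_ret < 0:
        raise ValueError("retention time must be nonnegative")
    if irf.is_analytic:
        peak = irf.rc.K1 + irf.rc.K3
        return float(impulse_response(irf.rc, t_ret)) / peak
    if t_ret > irf.times[-1] + _CONTIG_TOL:
        raise ValueError("retention time beyond sampled IRF support")
    if search_window is None:
        mask = np.ones(irf.times.size, dtype=bool)
    else:
        mask = (irf.times >= search_window[0]) & (irf.times <= search_window[1])
        if not np.any(mask):
            raise ValueError("search window contains no IRF samples")
    peak = float(np.max(irf.values[mask]))
    if peak <= 0:
        raise ValueError("retention undefined: nonpositive IRF maximum")
    return float(np.interp(t_ret, irf.times, irf.values)) / peak
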
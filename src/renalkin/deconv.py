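"""Frequency-domain convolution and regularized deconvolution.

The measured tissue curve y(t) is the convolution of the arterial input
x(t) with the tissue impulse response f(t).  Both the forward convolution
and its inversion are done with FFTs; the deconvolution is stabilized by
penalizing the third finite difference of the estimate,

    phi = conj(xi) * psi / (xi * conj(xi) + gamma * kappa * conj(kappa))

where xi, psi, phi are the transforms of x, y, f and kappa is the
transform of the third-difference operator c = [1, -3, 3, -1, 0, ...].
gamma scales the penalty; gamma = 1 is the literal regularized quotient,
gamma -> 0 recovers plain Fourier division.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetic_model import InputFunction, TimeActivityCurve

__all__ = [
    "UniformSignal",
    "RegularizerSpec",
    "THIRD_DIFFERENCE",
    "resample_uniform",
    "convolve_fft",
    "deconvolve_fft",
]

#: Third-difference operator coefficients (leading entries; the rest are 0).
THIRD_DIFFERENCE = np.array([1.0, -3.0, 3.0, -1.0])


@dataclass(frozen=True)
class UniformSignal:
    """A signal sampled on a uniform grid t0, t0+dt, ... (minutes)."""

    dt: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a nonempty 1-d array")
        if not np.all(np.isfinite(v)):
            raise ValueError("signal values must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class RegularizerSpec:
    """Third-difference regularizer with penalty weight gamma >= 0."""

    gamma: float = 1.0
    coefficients: np.ndarray = field(default_factory=lambda: THIRD_DIFFERENCE.copy())

    def __post_init__(self):
        if not (np.isfinite(self.gamma) and self.gamma >= 0):
            raise ValueError(f"gamma must be finite and >= 0, got {self.gamma}")
        c = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", c)


def resample_uniform(curve, dt: float, t_end: float | None = None,
                     kind: str = "linear") -> UniformSignal:
    """Resample a TAC (at frame mid-times) or input function onto a uniform grid.

    ``kind`` is "linear" (default) or "pchip" (shape-preserving cubic, exact
    at the support points like the linear rule but without the chord bias on
    smooth curves sampled by long frames).  The value is zero before the
    first support point, reached by a linear ramp from t = 0.  The grid runs
    from 0 to the last support point (or ``t_end`` if given, which must not
    exceed the support).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if kind not in ("linear", "pchip"):
        raise ValueError(f"unknown resampling kind {kind!r}")
    if isinstance(curve, TimeActivityCurve):
        t, v = curve.schedule.mid_times, curve.activity
    elif isinstance(curve, InputFunction):
        t, v = curve.times, curve.activity
    else:
        t = np.asarray(curve[0], dtype=float)
        v = np.asarray(curve[1], dtype=float)
    last = float(t[-1]) if t_end is None else float(t_end)
    if t_end is not None and t_end > t[-1] + 1e-9:
        raise ValueError("t_end exceeds the support of the curve")
    if dt > last:
        raise ValueError(f"dt = {dt:g} min exceeds the curve span {last:g} min")
    n = int(np.floor(last / dt + 1e-9)) + 1
    grid = dt * np.arange(n)
    if kind == "pchip":
        from scipy.interpolate import PchipInterpolator

        vals = np.asarray(PchipInterpolator(t, v)(np.clip(grid, t[0], t[-1])))
    else:
        vals = np.interp(grid, t, v)
    before = grid < t[0]
    vals[before] = np.interp(grid[before], np.array([0.0, t[0]]), np.array([0.0, v[0]]))
    return UniformSignal(dt=dt, values=vals, t0=0.0)


def _padded_length(n: int) -> int:
    return 1 << int(np.ceil(np.log2(max(2 * n, 2))))


def _check_dt(a: UniformSignal, b: UniformSignal) -> float:
    if abs(a.dt - b.dt) > 1e-12 * max(a.dt, b.dt):
        raise ValueError(f"dt mismatch: {a.dt} vs {b.dt}")
    return a.dt


def convolve_fft(x: UniformSignal, f: UniformSignal) -> UniformSignal:
    """Linear convolution y = x (*) f computed in the frequency domain.

    Signals are zero-padded to the next power of two at least twice the
    longer length, so circular wrap-around never contaminates the result.
    The Riemann scaling by dt makes the discrete result approximate the
    continuous convolution integral; output is truncated to x's support.
    """
    dt = _check_dt(x, f)
    nfft = _padded_length(max(len(x), len(f)))
    y = np.fft.irfft(np.fft.rfft(x.values, nfft) * np.fft.rfft(f.values, nfft), nfft)
    return UniformSignal(dt=dt, values=dt * y[: len(x)], t0=x.t0 + f.t0)


def deconvolve_fft(
    y: UniformSignal, x: UniformSignal, reg: RegularizerSpec | None = None
) -> UniformSignal:
    """Estimate the impulse response f from y = x (*) f.

    Implements the regularized frequency-domain quotient (third-difference
    penalty); with gamma = 0 this is exact Fourier division and inverts
    convolve_fft to round-off.  The inverse transform must be real; a
    nontrivial imaginary residue indicates an inconsistent problem.
    """
    reg = RegularizerSpec() if reg is None else reg
    dt = _check_dt(y, x)
    if not np.any(x.values != 0.0):
        raise ValueError("cannot deconvolve against an identically zero input")
    nfft = _padded_length(max(len(x), len(y)))
    xi = np.fft.fft(x.values, nfft)
    psi = np.fft.fft(y.values, nfft)
    kappa = np.fft.fft(reg.coefficients, nfft)
    denom = (xi * np.conj(xi)).real + reg.gamma * (kappa * np.conj(kappa)).real
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.conj(xi) * psi / denom
    phi[~np.isfinite(phi)] = 0.0
    fhat = np.fft.ifft(phi)
    return UniformSignal(dt=dt, values=fhat.real[: len(y)] / dt, t0=y.t0 - x.t0)


def third_difference_norm(values: np.ndarray) -> float:
    """L2 norm of the third finite difference — the quantity the regularizer damps."""
    return float(np.linalg.norm(np.diff(np.asarray(values, dtype=float), n=3)))
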
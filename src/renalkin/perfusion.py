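"""First-pass perfusion AUC ratios from water-bolus TACs.

Relative renal perfusion is quantified without arterial sampling: the two
kidneys' first-pass curves are integrated over a common window running
from bolus onset to the first peak, and their AUC ratio is reported with
the contralateral (or bilateral-average) kidney as the reference.  The
only absolute-flow computation is the hematocrit conversion of the total
first-pass uptake K1 + K3 into blood flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetic_model import TimeActivityCurve

__all__ = [
    "PerfusionResult",
    "perfusion_window",
    "perfusion_ratio",
    "flow_from_uptake",
]

#: Onset: first frame exceeding this fraction of the curve's own maximum.
ONSET_FRACTION = 0.05
#: A candidate first peak must exceed this fraction of the global maximum.
PEAK_FRACTION = 0.5


@dataclass(frozen=True)
class PerfusionResult:
    """AUC ratio of a test kidney against a reference over a common window."""

    window: tuple           # (t_onset, t_peak), minutes
    auc_test: float         # Bq*min/mL/MBq
    auc_ref: float
    ratio: float


def _first_peak_mid(tac: TimeActivityCurve) -> float:
    v = tac.activity
    mids = tac.schedule.mid_times
    peak = float(np.max(v))
    if peak <= 0:
        raise ValueError("cannot locate a peak in an all-zero curve")
    for i in range(1, v.size - 1):
        if v[i] >= v[i - 1] and v[i] >= v[i + 1] and v[i] > PEAK_FRACTION * peak:
            return float(mids[i])
    raise ValueError(
        f"curve {tac.label!r} has no interior first peak within the scan"
    )


def _onset_mid(tac: TimeActivityCurve) -> float:
    v = tac.activity
    thresh = ONSET_FRACTION * float(np.max(v))
    idx = np.nonzero(v > thresh)[0]
    if idx.size == 0:
        raise ValueError("no activity onset found")
    return float(tac.schedule.mid_times[idx[0]])


def perfusion_window(tacs, per_curve: bool = False):
    """Common [onset, first-peak] window for a set of water TACs (minutes).

    Onset is the earliest frame mid-time at which any curve exceeds 5% of
    its own maximum; the peak time is the earliest first local maximum over
    the curves (joint determination by default; ``per_curve`` returns one
    window per curve instead).
    """
    tacs = list(tacs)
    if not tacs:
        raise ValueError("need at least one curve")
    sched = tacs[0].schedule
    for t in tacs[1:]:
        if not np.allclose(t.schedule.mid_times, sched.mid_times):
            raise ValueError("curves must share a frame schedule")
    windows = []
    for t in tacs:
        onset, peak = _onset_mid(t), _first_peak_mid(t)
        if onset >= peak:
            raise ValueError(
                f"degenerate window for {t.label!r}: onset {onset:g} >= peak {peak:g}"
            )
        windows.append((onset, peak))
    if per_curve:
        return windows
    return (min(w[0] for w in windows), min(w[1] for w in windows))


def _auc(tac: TimeActivityCurve, window) -> float:
    """Trapezoidal AUC on frame mid-times, clipped at the window edges."""
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must satisfy t_onset < t_peak")
    mids = tac.schedule.mid_times
    t = np.concatenate(([lo], mids[(mids > lo) & (mids < hi)], [hi]))
    v = np.interp(t, mids, tac.activity)
    return float(np.trapezoid(v, t))


def perfusion_ratio(
    test: TimeActivityCurve, ref: TimeActivityCurve, window=None
) -> PerfusionResult:
    """AUC ratio test/reference over the common first-pass window."""
    if window is None:
        window = perfusion_window([test, ref])
    auc_t = _auc(test, window)
    auc_r = _auc(ref, window)
    if auc_r <= 0:
        raise ValueError("reference AUC is zero; ratio undefined")
    return PerfusionResult(window=tuple(window), auc_test=auc_t, auc_ref=auc_r,
                           ratio=auc_t / auc_r)


def flow_from_uptake(total_uptake: float, hematocrit: float, density: float = 1.0) -> float:
    """Convert total first-pass uptake K1 + K3 (mL/min/mL) to blood flow (mL/min/g).

    flow = uptake / ((1 - hematocrit) * density): the uptake refers to
    plasma, so dividing by the plasma fraction of blood (1 - Hct) and the
    tissue density gives whole-blood flow per gram.
    """
    if not 0.0 <= hematocrit < 1.0:
        raise ValueError(f"hematocrit must be in [0, 1), got {hematocrit}")
    if density <= 0:
        raise ValueError("density must be positive")
    if total_uptake < 0:
        raise ValueError("uptake must be nonnegative")
    return total_uptake / ((1.0 - hematocrit) * density)
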
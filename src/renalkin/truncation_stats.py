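"""Imaging-time truncation analysis and cohort statistics.

Shortening a dynamic PET acquisition truncates the data available to the
kinetic fit.  This module quantifies the cost: each kidney is refit using
only frames up to a series of mid-scan time points, the percent bias of
DVR (and of the retention parameter Y_ret) at each point is computed
against the full-data reference, and a principal-component factor
analysis with varimax rotation checks whether the across-kidney pattern
of the parameter is preserved at shortened times.  Group comparison
(t-tests, one-way ANOVA) and one-tailed Pearson correlation round out the
cohort-level reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitConfig, fit_convolution
from .kinetic_model import FrameSchedule, TimeActivityCurve, retention_from_tac

__all__ = [
    "DEFAULT_MIDSCAN_POINTS",
    "TruncationSeries",
    "FactorResult",
    "truncate_and_fit",
    "bias",
    "factor_analysis",
    "group_compare",
    "correlate",
]

#: Mid-scan time points (minutes); the last one is the full-data reference.
DEFAULT_MIDSCAN_POINTS = (42.5, 47.5, 52.5, 57.5, 62.5, 67.5, 72.5, 77.5, 82.5, 87.5)


@dataclass(frozen=True)
class TruncationSeries:
    """Per-kidney DVR and Y_ret at each mid-scan point (kidneys x points)."""

    points: np.ndarray
    dvr: np.ndarray
    y_ret: np.ndarray
    labels: list
    ok: np.ndarray          # per (kidney, point) fit-success flag

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if np.any(np.diff(pts) <= 0):
            raise ValueError("mid-scan points must be strictly increasing")

    @property
    def reference_index(self) -> int:
        return self.points.size - 1

    def bias_percent(self, which: str = "dvr") -> np.ndarray:
        """Signed percent bias of each point against the last-point reference."""
        vals = getattr(self, which)
        return np.array([bias(vals[:, j], vals[:, self.reference_index])
                         for j in range(self.points.size)])


def _truncated_tac(tac: TimeActivityCurve, t_mid: float) -> TimeActivityCurve:
    keep = tac.schedule.mid_times <= t_mid + 1e-9
    if not np.any(keep):
        raise ValueError(f"no frames at or before mid-scan point {t_mid:g} min")
    sched = FrameSchedule(tac.schedule.start_times[keep], tac.schedule.durations[keep])
    return TimeActivityCurve(sched, tac.activity[keep], label=tac.label)


def truncate_and_fit(studies, cfg: FitConfig | None = None,
                     points=DEFAULT_MIDSCAN_POINTS) -> TruncationSeries:
    """Refit each kidney at each mid-scan point with the convolution approach.

    At point t only frames with mid-time <= t enter; the fit window's upper
    edge is clipped to t, and Y_ret is recomputed as TAC(t) over the
    truncated curve's maximum.  A per-point failure is flagged (NaN), not
    fatal.  The last point is the full-data reference.
    """
    cfg = FitConfig() if cfg is None else cfg
    studies = list(studies)
    points = np.asarray(points, dtype=float)
    n, m = len(studies), points.size
    dvr = np.full((n, m), np.nan)
    yret = np.full((n, m), np.nan)
    ok = np.zeros((n, m), dtype=bool)
    for i, st in enumerate(studies):
        for j, t in enumerate(points):
            try:
                trunc = _truncated_tac(st.tac, t)
                cfg_t = replace(cfg, window=(cfg.window[0], min(cfg.window[1], float(t))),
                                t_ret=min(cfg.t_ret, float(t)))
                fit = fit_convolution(trunc, st.input_fn, cfg_t)
                dvr[i, j] = fit.binding.dvr
                yret[i, j] = retention_from_tac(trunc, min(float(t), trunc.schedule.mid_times[-1]))
                ok[i, j] = True
            except (ValueError, RuntimeError) as exc:
                warnings.warn(f"{st.label} @ {t:g} min: {exc}", stacklevel=2)
    return TruncationSeries(points=points, dvr=dvr, y_ret=yret,
                            labels=[st.label for st in studies], ok=ok)


def bias(values, refs) -> float:
    """Mean percent deviation of per-kidney values from their references.

    bias = 100/n * sum((value_m - ref_m) / ref_m); signed, so systematic
    over- and underestimation do not average away per kidney.
    """
    values = np.asarray(values, dtype=float)
    refs = np.asarray(refs, dtype=float)
    if values.shape != refs.shape:
        raise ValueError("values and refs must have equal length")
    if np.any(refs == 0):
        raise ValueError("zero reference value; bias undefined")
    return float(np.mean((values - refs) / refs) * 100.0)


@dataclass(frozen=True)
class FactorResult:
    """Loadings and explained variance of a rotated principal-component solution."""

    loadings: np.ndarray            # variables x factors
    variance_explained: np.ndarray  # per factor, fraction of total variance
    total_variance_explained: float
    rotation: str = "varimax"

    @property
    def communalities(self) -> np.ndarray:
        return np.sum(self.loadings**2, axis=1)


def _varimax(loadings: np.ndarray, max_sweeps: int = 500, tol: float = 1e-12,
             kaiser: bool = True) -> np.ndarray:
    """Varimax rotation (orthogonal), with Kaiser row normalization.

    Classic pairwise planar rotations with the closed-form optimal angle.
    When the criterion is flat (e.g. a rank-one loading pattern) the angle
    formula returns zero and the loadings are left unrotated, which is the
    conventional behaviour.
    """
    L = loadings.copy()
    p, k = L.shape
    if k < 2:
        return L
    h = np.sqrt(np.sum(L**2, axis=1))
    h_safe = np.where(h > 0, h, 1.0)
    if kaiser:
        L = L / h_safe[:, None]
    for _ in range(max_sweeps):
        max_angle = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = L[:, i], L[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                num = 2.0 * (np.sum(u * v) - np.sum(u) * np.sum(v) / p)
                den = np.sum(u**2 - v**2) - (np.sum(u) ** 2 - np.sum(v) ** 2) / p
                if np.hypot(num, den) <= 1e-7 * p:
                    # criterion stationary in this plane (e.g. rank-one
                    # pattern): keep the principal orientation
                    continue
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) > tol:
                    c, s = np.cos(phi), np.sin(phi)
                    L[:, i], L[:, j] = c * x + s * y, -s * x + c * y
                max_angle = max(max_angle, abs(phi))
        if max_angle <= tol:
            break
    if kaiser:
        L = L * h_safe[:, None]
    # rotation may permute factors: reorder by explained variance, then fix
    # signs so each factor's largest-magnitude loading is positive
    order = np.argsort(-np.sum(L**2, axis=0), kind="stable")
    L = L[:, order]
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    return L * signs


def factor_analysis(data, n_factors: int = 2) -> FactorResult:
    """Principal-component factor analysis of a kidneys x time-points matrix.

    Columns are standardized, the leading eigenvectors of their correlation
    matrix are scaled by the square roots of the eigenvalues to give
    loadings, and the loadings are varimax-rotated.  Orthogonal rotation
    preserves communalities and total explained variance.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-d matrix with at least 3 rows (kidneys)")
    if np.any(~np.isfinite(X)):
        raise ValueError("data matrix contains non-finite entries")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        cols = np.nonzero(sd == 0)[0]
        raise ValueError(f"constant column(s) {cols.tolist()}: correlation undefined")
    if n_factors < 1 or n_factors > X.shape[1]:
        raise ValueError("n_factors must be between 1 and the number of columns")
    corr = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    loadings = eigvec[:, :n_factors] * np.sqrt(eigval[:n_factors])
    loadings = _varimax(loadings)
    var_per = np.sum(loadings**2, axis=0) / X.shape[1]
    return FactorResult(
        loadings=loadings,
        variance_explained=var_per,
        total_variance_explained=float(np.sum(var_per)),
    )


def group_compare(groups: dict, welch: bool = False, control: str = "C",
                  paired: tuple = ("IR", "CL")) -> pd.DataFrame:
    """Two-way t-tests, a paired t-test, and one-way ANOVA per parameter.

    ``groups`` maps group name -> DataFrame (kidneys x parameters, shared
    columns).  Simple t-tests compare each non-control group against the
    control (pooled variance by default, Welch by flag); the ``paired``
    groups are compared with a paired t-test by row order; ANOVA spans all
    groups.  Groups with a single observation yield NaN with a warning.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    cols = list(groups[names[0]].columns)
    for g in names[1:]:
        if list(groups[g].columns) != cols:
            raise ValueError("groups must share parameter columns")
    for g, df in groups.items():
        if len(df) < 2:
            warnings.warn(f"group {g!r} has a single observation; its tests are NaN",
                          stacklevel=2)
    rows = {}
    for col in cols:
        row = {}
        c = groups[control][col].to_numpy() if control in groups else None
        for g in names:
            if g == control or c is None:
                continue
            v = groups[g][col].to_numpy()
            if len(v) < 2 or len(c) < 2:
                t, p = np.nan, np.nan
            else:
                t, p = stats.ttest_ind(v, c, equal_var=not welch)
            row[f"t_{g}_vs_{control}"] = t
            row[f"p_{g}_vs_{control}"] = p
        a, b = paired
        if a in groups and b in groups and len(groups[a]) == len(groups[b]) >= 2:
            t, p = stats.ttest_rel(groups[a][col].to_numpy(), groups[b][col].to_numpy())
            row[f"t_paired_{a}_vs_{b}"] = t
            row[f"p_paired_{a}_vs_{b}"] = p
        samples = [groups[g][col].to_numpy() for g in names]
        if all(len(s) >= 2 for s in samples) and len(samples) >= 2:
            if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
                f, p = 0.0, 1.0
            else:
                f, p = stats.f_oneway(*samples)
        else:
            f, p = np.nan, np.nan
        row["anova_F"] = f
        row["anova_p"] = p
        rows[col] = row
    return pd.DataFrame(rows).T


def correlate(a, b):
    """One-tailed Pearson correlation (alternative: positive association)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    res = stats.pearsonr(a, b, alternative="greater")
    return float(res.statistic), float(res.pvalue)
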
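"""Entrainment statistics from multichannel voltage traces.

All metrics operate on uniformly sampled voltage matrices (samples x cells),
either produced by :mod:`gmnsim.simulate` or loaded from CSV, so recordings
from other sources can be analyzed with the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks as _scipy_find_peaks

__all__ = [
    "EntrainmentMetrics",
    "detect_peaks",
    "cell_periods",
    "lags",
    "entrainment_range",
    "compute_metrics",
    "fit_frequency_beta",
    "fit_lag_vs_coupling",
    "read_traces_csv",
]

#: Default peak-detection settings: robust to plateau-phase ripple given
#: slow-wave periods of ~16 s and larger in all regimes.
MIN_PROMINENCE_MV = 5.0
MIN_SEPARATION_S = 5.0

#: Default entrainment-classification thresholds (fractions).
PERIOD_CV_TOL = 0.005    # period s.d. / mean within a cell
PERIOD_MATCH_TOL = 0.01  # |period_i - period_1| / period_1
LAG_SD_TOL = 0.02        # relative-lag s.d. / period


def detect_peaks(time, trace, min_prominence_mV: float = MIN_PROMINENCE_MV,
                 min_separation_s: float = MIN_SEPARATION_S) -> np.ndarray:
    """Times (s) of prominent local maxima of a uniformly sampled trace.

    Peak times are refined by quadratic interpolation through the three
    samples around each detected maximum.
    """
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if time.size == 0 or trace.size == 0:
        raise ValueError("empty trace")
    if time.shape != trace.shape:
        raise ValueError("time and trace must have the same length")
    if time.size < 3:
        return np.empty(0)
    dt = time[1] - time[0]
    idx, _ = _scipy_find_peaks(trace, prominence=min_prominence_mV,
                               distance=max(int(round(min_separation_s / dt)), 1))
    out = np.empty(idx.size)
    for k, i in enumerate(idx):
        if 0 < i < trace.size - 1:
            denom = trace[i - 1] - 2.0 * trace[i] + trace[i + 1]
            shift = 0.5 * (trace[i - 1] - trace[i + 1]) / denom if denom != 0 else 0.0
            shift = np.clip(shift, -0.5, 0.5)
        else:
            shift = 0.0
        out[k] = time[i] + shift * dt
    return out


def cell_periods(peak_times, last_k: int = 7) -> dict:
    """Mean and s.d. of the last ``last_k`` inter-peak intervals of one cell.

    Cells with too few peaks are flagged (``valid=False``) rather than
    dropped; their statistics are NaN.
    """
    pt = np.asarray(peak_times, dtype=float)
    if pt.size < last_k + 1:
        return {"mean": np.nan, "sd": np.nan, "n": max(pt.size - 1, 0),
                "valid": False}
    d = np.diff(pt)[-last_k:]
    return {"mean": float(d.mean()), "sd": float(d.std()), "n": int(d.size),
            "valid": True}


def lags(peaks_per_cell, last_k: int = 7, period: float | None = None) -> dict:
    """Relative lags of every cell against cell 1 over the last ``last_k``
    cycles of cell 1.

    Each reference peak of cell 1 is matched to the nearest subsequent peak
    of cell i within one period; unmatched cycles near the record end are
    discarded and counted.  Returns per-cycle relative lags (``last_k`` x N,
    NaN where unmatched), their per-cell mean/s.d., and the total lag
    (relative lag of the last cell).
    """
    peaks = [np.asarray(p, dtype=float) for p in peaks_per_cell]
    n = len(peaks)
    if n == 0 or peaks[0].size < 2:
        raise ValueError("need at least one cell with two peaks")
    if period is None:
        period = float(np.diff(peaks[0]).mean())
    refs = peaks[0][-last_k:]
    rel = np.full((refs.size, n), np.nan)
    discarded = 0
    for j, tp in enumerate(refs):
        for i in range(n):
            later = peaks[i][(peaks[i] >= tp) & (peaks[i] <= tp + period)]
            if later.size:
                rel[j, i] = later[0] - tp  # nearest subsequent; earliest wins
            else:
                discarded += 1
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(rel, axis=0)
        sd = np.nanstd(rel, axis=0)
    total = rel[:, -1]
    total = total[np.isfinite(total)]
    return {
        "relative_lag": rel,
        "relative_lag_mean": mean,
        "relative_lag_sd": sd,
        "total_lag_mean": float(total.mean()) if total.size else np.nan,
        "total_lag_sd": float(total.std()) if total.size else np.nan,
        "discarded": int(discarded),
        "period": period,
    }


def entrainment_range(peaks_per_cell, last_k: int = 20,
                      period_cv_tol: float = PERIOD_CV_TOL,
                      period_match_tol: float = PERIOD_MATCH_TOL,
                      lag_sd_tol: float = LAG_SD_TOL) -> dict:
    """Per-cell entrained flags and the contiguous entrained rostral prefix.

    Cell i is entrained iff, over the last ``last_k`` cycles: (a) its period
    s.d./mean is below ``period_cv_tol``, (b) its period matches cell 1
    within ``period_match_tol``, and (c) its relative-lag s.d. is below
    ``lag_sd_tol`` of the period.
    """
    peaks = [np.asarray(p, dtype=float) for p in peaks_per_cell]
    n = len(peaks)
    stats = [cell_periods(p, last_k=last_k) for p in peaks]
    L = lags(peaks, last_k=last_k)
    p1 = stats[0]["mean"]
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        s = stats[i]
        if not s["valid"] or not np.isfinite(p1) or p1 <= 0:
            continue
        ok = (s["sd"] / s["mean"] < period_cv_tol
              and abs(s["mean"] - p1) / p1 < period_match_tol)
        if ok:
            nfin = np.sum(np.isfinite(L["relative_lag"][:, i]))
            ok = nfin >= max(last_k // 2, 2) and \
                L["relative_lag_sd"][i] < lag_sd_tol * p1
        flags[i] = ok
    prefix = 0
    for f in flags:
        if not f:
            break
        prefix += 1
    return {"entrained": flags, "range": int(prefix)}


@dataclass
class EntrainmentMetrics:
    """Summary statistics of one multichannel voltage record."""

    peak_times: list            # per-cell refined peak times (s)
    period_mean: np.ndarray     # per-cell, last-k cycles (s)
    period_sd: np.ndarray
    period_valid: np.ndarray    # per-cell flag: enough peaks for statistics
    relative_lag_mean: np.ndarray
    relative_lag_sd: np.ndarray
    total_lag_mean: float
    total_lag_sd: float
    velocity_cm_s: float        # NaN unless the whole chain is entrained
    entrained: np.ndarray       # per-cell classification over last 20 cycles
    entrainment_range: int      # contiguous entrained prefix from cell 1
    v_min: np.ndarray           # per-cell voltage minimum over the window (mV)
    discarded_cycles: int

    @property
    def n_units(self) -> int:
        return self.period_mean.size


def compute_metrics(time, v, length_cm: float = 6.0,
                    transient_s: float = 300.0, last_k: int = 7,
                    map_k: int = 20,
                    min_prominence_mV: float = MIN_PROMINENCE_MV,
                    min_separation_s: float = MIN_SEPARATION_S,
                    period_cv_tol: float = PERIOD_CV_TOL,
                    period_match_tol: float = PERIOD_MATCH_TOL,
                    lag_sd_tol: float = LAG_SD_TOL) -> EntrainmentMetrics:
    """All entrainment metrics of a (samples x cells) voltage matrix.

    The first ``transient_s`` seconds are discarded.  Period and lag
    summaries use the last ``last_k`` cycles; entrainment classification and
    voltage minima use the last ``map_k`` cycles.
    """
    time = np.asarray(time, dtype=float)
    v = np.asarray(v, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    keep = time >= transient_s
    t = time[keep]
    v = v[keep]
    n = v.shape[1]
    peaks = [detect_peaks(t, v[:, i], min_prominence_mV, min_separation_s)
             for i in range(n)]
    stats = [cell_periods(p, last_k=last_k) for p in peaks]
    L = lags(peaks, last_k=last_k)
    E = entrainment_range(peaks, last_k=map_k, period_cv_tol=period_cv_tol,
                          period_match_tol=period_match_tol,
                          lag_sd_tol=lag_sd_tol)
    period_mean = np.array([s["mean"] for s in stats])
    # voltage minima over the last map_k cycles of cell 1
    p1 = stats[0]["mean"]
    window = map_k * p1 if np.isfinite(p1) else (t[-1] - t[0])
    tail = t >= t[-1] - window
    v_min = v[tail].min(axis=0)
    entrained_all = E["range"] == n
    velocity = (length_cm / L["total_lag_mean"]
                if entrained_all and L["total_lag_mean"] and
                np.isfinite(L["total_lag_mean"]) and L["total_lag_mean"] > 0
                else np.nan)
    return EntrainmentMetrics(
        peak_times=peaks,
        period_mean=period_mean,
        period_sd=np.array([s["sd"] for s in stats]),
        period_valid=np.array([s["valid"] for s in stats]),
        relative_lag_mean=L["relative_lag_mean"],
        relative_lag_sd=L["relative_lag_sd"],
        total_lag_mean=L["total_lag_mean"],
        total_lag_sd=L["total_lag_sd"],
        velocity_cm_s=velocity,
        entrained=E["entrained"],
        entrainment_range=E["range"],
        v_min=v_min,
        discarded_cycles=L["discarded"],
    )


def fit_frequency_beta(frequencies_cpm, betas):
    """Ordinary least squares of frequency (cpm) on innervation drive beta.

    Returns (slope, intercept, r_squared).
    """
    f = np.asarray(frequencies_cpm, dtype=float)
    b = np.asarray(betas, dtype=float)
    if f.size != b.size or f.size < 2:
        raise ValueError("need at least 2 matching (frequency, beta) points")
    if np.ptp(b) == 0:
        raise ValueError("degenerate beta vector (all values equal)")
    A = np.vstack([b, np.ones_like(b)]).T
    coef, *_ = np.linalg.lstsq(A, f, rcond=None)
    resid = f - A @ coef
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(coef[0]), float(coef[1]), r2


def _double_exp(x, a1, b1, a2, b2):
    return a1 * np.exp(-x / b1) + a2 * np.exp(-x / b2)


def fit_lag_vs_coupling(coupling_values, total_lags, n_starts: int = 16):
    """Fit ``y = a1 exp(-x/b1) + a2 exp(-x/b2)`` by multi-start nonlinear
    least squares.

    Returns a dict with parameters (a1, b1, a2, b2), the residual sum of
    squares, and a boundary flag set when a decay constant reaches the
    search bound (e.g. for constant data, where one term degenerates to a
    constant with b2 -> infinity).  Raises on non-convergence, reporting the
    residuals of the best attempt.
    """
    x = np.asarray(coupling_values, dtype=float)
    y = np.asarray(total_lags, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need at least 5 (coupling, lag) points")
    scale = max(x.max(), 1e-12)
    b_hi = 1e8 * scale
    rng = np.random.default_rng(0)
    best = None
    attempts = []
    inits = [(y.max(), 0.1 * scale, y.min(), scale),
             (y.max() - y.min(), 0.3 * scale, y.min(), 10.0 * scale),
             (0.5 * y.max(), scale, 0.5 * y.max(), 5.0 * scale)]
    while len(inits) < n_starts:
        inits.append((rng.uniform(0, 2 * max(abs(y).max(), 1.0)),
                      scale * 10 ** rng.uniform(-2, 2),
                      rng.uniform(0, 2 * max(abs(y).max(), 1.0)),
                      scale * 10 ** rng.uniform(-2, 4)))
    for p0 in inits:
        try:
            popt, _ = curve_fit(_double_exp, x, y, p0=p0, maxfev=20000,
                                bounds=([-np.inf, 1e-12 * scale, -np.inf,
                                         1e-12 * scale],
                                        [np.inf, b_hi, np.inf, b_hi]))
        except Exception:
            continue
        res = y - _double_exp(x, *popt)
        sse = float(np.sum(res ** 2))
        attempts.append((sse, popt, res))
        if best is None or sse < best[0]:
            best = (sse, popt, res)
    if best is None:
        raise RuntimeError("double-exponential fit did not converge from any "
                           "starting point")
    sse, popt, res = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0 and sse > 0.25 * ss_tot:
        raise RuntimeError(
            "double-exponential fit did not converge: best residual sum of "
            f"squares {sse:.4g} against total {ss_tot:.4g}; residuals {res}")
    a1, b1, a2, b2 = (float(v) for v in popt)
    boundary = bool(b1 > 0.99 * b_hi or b2 > 0.99 * b_hi)
    return {"a1": a1, "b1": b1, "a2": a2, "b2": b2, "sse": sse,
            "boundary": boundary}


def read_traces_csv(path):
    """Load a multichannel voltage CSV (a time column plus one column per
    cell) and return (time, voltage matrix)."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("traces CSV needs a time column plus >=1 cell column")
    time = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1:].to_numpy(dtype=float)
    return time, v
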
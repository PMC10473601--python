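"""Field-potential train analysis: I/O curves, paired-pulse ratio, train
normalization, charge transfer, post-train recovery and readily-releasable
pool (RRP) estimation.

The RRP estimate follows the train back-extrapolation method: responses in
a depressing train are normalized to the first response, cumulatively
summed, a line is fitted over the steady-state portion where depletion and
replenishment balance, and its y-intercept (in multiples of the first
response) is the RRP proxy. On the raw scale intercept x A1 approximates
Nq, the product of release-site number and quantal size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TrainRecording",
    "IOCurve",
    "RrpEstimate",
    "RecoveryCurve",
    "io_curve",
    "paired_pulse_ratio",
    "normalize_train",
    "phase_means",
    "rrp_back_extrapolation",
    "recovery_curve",
    "charge_transfer",
]


@dataclass
class TrainRecording:
    """Stimulus-locked response amplitudes for one train."""

    stimulus_times: np.ndarray  # s
    amplitudes: np.ndarray  # fEPSP peak or slope, a.u.
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(np.diff(self.stimulus_times) <= 0):
            raise ValueError("stimulus_times must be strictly increasing")
        if len(self.stimulus_times) != len(self.amplitudes):
            raise ValueError("stimulus_times and amplitudes must have equal length")


@dataclass
class IOCurve:
    """Input–output relation: fEPSP slope vs fiber-volley amplitude."""

    fiber_volley: np.ndarray
    fepsp_slope: np.ndarray
    slope: float
    intercept: float
    r_squared: float


@dataclass
class RrpEstimate:
    intercept: float  # normalized cumulative units (Nq / A1 on the raw scale)
    steady_slope: float  # per-stimulus replenishment, normalized units
    window: tuple[int, int]  # 1-based inclusive stimulus indices used
    r_squared: float
    steady: bool  # False if the window shows residual curvature


@dataclass
class RecoveryCurve:
    intervals: np.ndarray  # s after train end
    normalized_amplitudes: np.ndarray
    baseline: float


def io_curve(fiber_volley, fepsp_slope) -> IOCurve:
    """Ordinary least-squares line of fEPSP slope against fiber-volley amplitude."""
    x = np.asarray(fiber_volley, dtype=float)
    y = np.asarray(fepsp_slope, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need >= 2 paired (fiber volley, fEPSP slope) points")
    if np.ptp(x) == 0:
        raise ValueError("all fiber-volley amplitudes identical; line undefined")
    res = sps.linregress(x, y)
    return IOCurve(fiber_volley=x, fepsp_slope=y, slope=float(res.slope),
                   intercept=float(res.intercept), r_squared=float(res.rvalue**2))


def paired_pulse_ratio(peak1: float, peak2: float, interval: float | None = None) -> float:
    """Second-pulse peak divided by first-pulse peak."""
    if not peak1 > 0:
        raise ValueError(f"first peak must be > 0, got {peak1}")
    return float(peak2) / float(peak1)


def normalize_train(amplitudes) -> np.ndarray:
    """Divide every amplitude by the first; the first element becomes 1."""
    a = np.asarray(amplitudes, dtype=float)
    if len(a) == 0 or a[0] == 0:
        raise ValueError("first amplitude must be nonzero to normalize")
    return a / a[0]


def phase_means(normalized) -> tuple[float, float]:
    """Means of the first 10 and last 10 normalized responses."""
    a = np.asarray(normalized, dtype=float)
    if len(a) < 20:
        raise ValueError(f"train too short for phase means: {len(a)} < 20 stimuli")
    return float(a[:10].mean()), float(a[-10:].mean())


def rrp_back_extrapolation(
    normalized,
    steady_window: tuple[int, int] | None = None,
    *,
    curvature_tolerance: float = 0.05,
) -> RrpEstimate:
    """Back-extrapolate cumulative normalized responses to the y-axis.

    ``steady_window`` gives 1-based inclusive stimulus indices over which
    the cumulative curve is fitted (default: the last 30 stimuli). The fit
    is OLS of C_k = sum_{i<=k} normalized_i against k; the y-intercept is
    the RRP in multiples of the first response and the slope the
    steady-state replenishment per stimulus. The window is flagged
    non-steady when first- and second-half slopes differ by more than
    ``curvature_tolerance`` (relative to the mean response level).
    """
    a = np.asarray(normalized, dtype=float)
    n = len(a)
    if steady_window is None:
        steady_window = (max(1, n - 29), n)
    lo, hi = steady_window
    if not (1 <= lo < hi <= n):
        raise ValueError(f"steady_window {steady_window} outside train of {n} stimuli")
    if hi - lo + 1 < 5:
        raise ValueError("steady_window must contain >= 5 points")
    cum = np.cumsum(a)
    k = np.arange(1, n + 1, dtype=float)
    sel = slice(lo - 1, hi)
    res = sps.linregress(k[sel], cum[sel])
    # curvature check: compare slopes of the two window halves
    mid = (lo + hi) // 2
    s1 = sps.linregress(k[lo - 1:mid], cum[lo - 1:mid]).slope
    s2 = sps.linregress(k[mid - 1:hi], cum[mid - 1:hi]).slope
    scale = max(abs(res.slope), np.mean(np.abs(a)) if np.any(a) else 1.0, 1e-12)
    steady = abs(s1 - s2) <= curvature_tolerance * max(scale, 1e-12)
    return RrpEstimate(
        intercept=float(res.intercept),
        steady_slope=float(res.slope),
        window=(lo, hi),
        r_squared=float(res.rvalue**2) if np.ptp(cum[sel]) > 0 else 1.0,
        steady=bool(steady),
    )


def recovery_curve(intervals, amplitudes, baseline: float) -> RecoveryCurve:
    """Post-train single-pulse amplitudes normalized to the pre-train baseline."""
    iv = np.asarray(intervals, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if np.any(np.diff(iv) <= 0):
        raise ValueError("intervals must be strictly increasing")
    if not baseline > 0:
        raise ValueError(f"baseline must be > 0, got {baseline}")
    if len(iv) != len(amps):
        raise ValueError("intervals and amplitudes must have equal length")
    return RecoveryCurve(intervals=iv, normalized_amplitudes=amps / baseline, baseline=baseline)


def charge_transfer(
    trace_times,
    trace_values,
    stimulus_times,
    sync_window: float = 0.010,
) -> tuple[float, float, float]:
    """Total, synchronous and asynchronous charge over a train.

    The trace must already be baseline subtracted. Total charge is the
    trapezoidal integral of |trace| over the train span; synchronous charge
    sums the integrals over ``[t_i, t_i + sync_window]`` after each
    stimulus; asynchronous is the remainder, so the three satisfy
    total = synchronous + asynchronous exactly.
    """
    t = np.asarray(trace_times, dtype=float)
    v = np.abs(np.asarray(trace_values, dtype=float))
    stim = np.asarray(stimulus_times, dtype=float)
    if len(stim) > 1:
        isi = np.min(np.diff(stim))
        if sync_window >= isi:
            raise ValueError(f"sync_window {sync_window} s >= inter-stimulus interval {isi} s")
    t_end = stim[-1] + (np.min(np.diff(stim)) if len(stim) > 1 else sync_window)
    span = (t >= stim[0]) & (t <= t_end)
    if not np.any(span):
        raise ValueError("trace does not cover the stimulus train")
    total = float(np.trapezoid(v[span], t[span]))
    sync = 0.0
    for ts in stim:
        w = (t >= ts) & (t <= ts + sync_window)
        if np.count_nonzero(w) > 1:
            sync += float(np.trapezoid(v[w], t[w]))
    sync = min(sync, total)
    return total, sync, total - sync
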
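"""Condensate dynamics: dispersion index, FRAP recovery fitting, ROI time courses.

The dispersion index used here is variance divided by mean of an axonal
intensity line profile — high for punctate (condensed) signal and low for
diffuse signal. FRAP traces are reduced to fractional recovery and fitted
with a one-phase association model ``f(t) = plateau * (1 - exp(-t / tau))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "LineProfile",
    "DispersionResult",
    "FrapTrace",
    "FrapFit",
    "line_dispersion",
    "normalize_dispersion",
    "fractional_recovery",
    "fit_one_phase",
    "stimulus_timecourse",
    "TimecourseSummary",
]


@dataclass
class LineProfile:
    """Width-averaged intensity values along a line drawn down an axon."""

    intensities: np.ndarray
    condition: str = ""
    axon_id: str = ""
    channel: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or len(self.intensities) < 2:
            raise ValueError("intensities must be a 1-D sequence of length >= 2")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class DispersionResult:
    axon_id: str
    condition: str
    cv_raw: float  # variance / mean, intensity units
    cv_normalized: float | None = None  # / condition mean CV


@dataclass
class FrapTrace:
    """Raw FRAP time series; ``bleach_frame`` indexes the first bleached frame."""

    times: np.ndarray  # s
    intensities: np.ndarray  # a.u.
    bleach_frame: int
    bleach_diameter: float = 800.0  # nm

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.times) != len(self.intensities):
            raise ValueError("times and intensities must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 <= self.bleach_frame < len(self.times):
            raise ValueError(f"bleach_frame {self.bleach_frame} outside trace")


@dataclass
class FrapFit:
    tau: float
    plateau: float
    residual_norm: float
    converged: bool


def line_dispersion(profile: LineProfile, *, cv_definition: str = "variance_over_mean") -> float:
    """Dispersion index of a line profile.

    Default is the index of dispersion, population variance divided by mean
    (in intensity units); ``cv_definition='sd_over_mean'`` gives the
    dimensionless classical coefficient of variation instead.
    """
    vals = profile.intensities
    mean = float(np.mean(vals))
    if mean <= 0:
        raise ValueError("mean intensity must be > 0 to compute dispersion")
    var = float(np.var(vals))  # population variance
    if cv_definition == "variance_over_mean":
        return var / mean
    if cv_definition == "sd_over_mean":
        return np.sqrt(var) / mean
    raise ValueError(f"unknown cv_definition {cv_definition!r}")


def normalize_dispersion(results: list[DispersionResult]) -> list[DispersionResult]:
    """Divide each axon's CV by the mean CV of its condition.

    By construction the normalized values average to exactly 1 within each
    condition.
    """
    if not results:
        raise ValueError("no dispersion results to normalize")
    by_cond: dict[str, list[float]] = {}
    for r in results:
        by_cond.setdefault(r.condition, []).append(r.cv_raw)
    means = {c: float(np.mean(v)) for c, v in by_cond.items()}
    for c, m in means.items():
        if m == 0:
            raise ValueError(f"condition {c!r} has zero mean CV; cannot normalize")
    return [
        DispersionResult(r.axon_id, r.condition, r.cv_raw, cv_normalized=r.cv_raw / means[r.condition])
        for r in results
    ]


def fractional_recovery(trace: FrapTrace) -> FrapTrace:
    """Rescale a bleached trace to fractional recovery.

    ``f(t) = (F(t) - F_floor) / (F_maxpost - F_floor)`` where ``F_floor`` is
    the first post-bleach frame and ``F_maxpost`` the maximum post-bleach
    intensity; the floor frame maps to 0 and the maximum to 1. Invariant to
    affine rescaling (gain/offset) of the raw trace. Only post-bleach frames
    are returned, with time zeroed at the bleach frame.
    """
    post = trace.intensities[trace.bleach_frame:]
    if len(post) < 2:
        raise ValueError("need at least 2 post-bleach frames")
    floor = post[0]
    max_post = float(np.max(post))
    if max_post == floor:
        raise ValueError("no recovery signal: post-bleach maximum equals the bleach floor")
    f = (post - floor) / (max_post - floor)
    t = trace.times[trace.bleach_frame:] - trace.times[trace.bleach_frame]
    return FrapTrace(times=t, intensities=f, bleach_frame=0,
                     bleach_diameter=trace.bleach_diameter)


def _one_phase(t, plateau, tau):
    return plateau * (1.0 - np.exp(-t / tau))


def fit_one_phase(trace: FrapTrace) -> FrapFit:
    """Least-squares fit of the one-phase association model to a
    fractional-recovery trace.

    Initialization is deterministic: plateau at the trace maximum, tau at
    the time to half-maximum. Non-convergence is flagged, never silently
    replaced by defaults.
    """
    t = trace.times[trace.bleach_frame:] - trace.times[trace.bleach_frame]
    f = trace.intensities[trace.bleach_frame:]
    if len(t) < 5:
        raise ValueError("need >= 5 post-bleach points to fit")
    p0_plateau = max(float(np.max(f)), 1e-6)
    half = p0_plateau / 2.0
    above = np.nonzero(f >= half)[0]
    p0_tau = float(t[above[0]]) if len(above) and t[above[0]] > 0 else float(t[-1]) / 4.0
    p0_tau = max(p0_tau, float(t[1] - t[0]) / 10.0)
    try:
        popt, _ = curve_fit(_one_phase, t, f, p0=[p0_plateau, p0_tau],
                            bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=10_000)
        plateau, tau = float(popt[0]), float(popt[1])
        resid = float(np.linalg.norm(f - _one_phase(t, plateau, tau)))
        return FrapFit(tau=tau, plateau=plateau, residual_norm=resid, converged=True)
    except RuntimeError:
        return FrapFit(tau=np.nan, plateau=np.nan, residual_norm=np.nan, converged=False)


@dataclass
class TimecourseSummary:
    """Cohort summary of stimulus-evoked ROI intensity changes (dF/F0)."""

    times: np.ndarray
    mean: np.ndarray  # mean dF/F0 per frame
    sem: np.ndarray
    per_roi: np.ndarray  # (n_roi, n_frames) dF/F0
    minimum_during_stim: float
    recovery_fraction: float  # share of the dip recovered after stimulation


def stimulus_timecourse(
    roi_traces: np.ndarray,
    times: np.ndarray,
    stimulus_interval: tuple[float, float],
    *,
    recovery_tail_frames: int = 5,
) -> TimecourseSummary:
    """Baseline-normalized ROI time courses around a stimulation window.

    dF/F0 uses the per-ROI pre-stimulus mean as F0. The reported minimum is
    the minimum of the cohort-mean trace during stimulation; the recovery
    fraction is how far the cohort mean returns from that minimum toward
    baseline (0), measured over the last ``recovery_tail_frames`` frames.
    """
    traces = np.atleast_2d(np.asarray(roi_traces, dtype=float))
    times = np.asarray(times, dtype=float)
    if traces.shape[1] != len(times):
        raise ValueError("roi_traces and times length mismatch")
    t0, t1 = stimulus_interval
    if not (times[0] <= t0 < t1 <= times[-1]):
        raise ValueError("stimulus interval outside the shared time base")
    pre = times < t0
    if not np.any(pre):
        raise ValueError("no pre-stimulus frames for baseline")
    f0 = traces[:, pre].mean(axis=1)
    if np.any(f0 == 0):
        raise ValueError("zero baseline in at least one ROI")
    dff = (traces - f0[:, None]) / f0[:, None]
    mean = dff.mean(axis=0)
    n = traces.shape[0]
    sem = dff.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(len(times), np.nan)
    during = (times >= t0) & (times <= t1)
    minimum = float(mean[during].min())
    tail = mean[-recovery_tail_frames:]
    recovery = float((tail.mean() - minimum) / (0.0 - minimum)) if minimum < 0 else np.nan
    return TimecourseSummary(times=times, mean=mean, sem=sem, per_roi=dff,
                             minimum_during_stim=minimum, recovery_fraction=recovery)


def dispersion_table(results: list[DispersionResult]) -> pd.DataFrame:
    """Tidy per-axon dispersion table."""
    return pd.DataFrame(
        [{"axon_id": r.axon_id, "condition": r.condition,
          "cv_raw": r.cv_raw, "cv_normalized": r.cv_normalized} for r in results]
    )
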
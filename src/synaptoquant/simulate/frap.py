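"""Synthetic FRAP traces following one-phase exponential association."""

from __future__ import annotations

import numpy as np

from ..condensate import FrapTrace

__all__ = ["generate_frap_trace"]


def generate_frap_trace(
    tau: float,
    plateau: float,
    noise_sd: float = 0.0,
    frame_interval: float = 0.6,
    n_frames: int = 100,
    bleach_frame: int = 3,
    seed: int | None = None,
    bleach_diameter: float = 800.0,
) -> FrapTrace:
    """One-phase-association recovery trace with additive Gaussian noise.

    Pre-bleach frames are at 1.0; from the bleach frame onward the signal is
    ``plateau * (1 - exp(-t / tau))`` with t measured from the bleach frame,
    plus N(0, noise_sd) per frame. Defaults mirror a 600-ms frame interval,
    100-frame acquisition bleached after frame 3.
    """
    if not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if not 0 < plateau <= 1:
        raise ValueError(f"plateau must be in (0, 1], got {plateau}")
    if not 0 <= bleach_frame < n_frames:
        raise ValueError(f"bleach_frame {bleach_frame} outside trace of {n_frames} frames")
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * frame_interval
    values = np.ones(n_frames)
    t_post = times[bleach_frame:] - times[bleach_frame]
    values[bleach_frame:] = plateau * (1.0 - np.exp(-t_post / tau))
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_frames)
    return FrapTrace(times=times, intensities=values, bleach_frame=bleach_frame,
                     bleach_diameter=bleach_diameter)
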
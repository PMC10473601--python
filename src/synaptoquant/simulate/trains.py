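"""Depletion–replenishment release model for depressing stimulus trains.

A pool of N release sites starts full; each pulse releases a fraction p of
the currently occupied sites, producing a field response q * p * P_i. Between
pulses the pool recovers toward N with first-order rate ``k_rep``:

    P_1 = N
    A_i = q * p * P_i  (+ Gaussian noise)
    P_{i+1} = P_i (1 - p) + (N - P_i (1 - p)) * (1 - exp(-dt * k_rep))

This is the minimal model whose cumulative normalized responses admit the
linear back-extrapolation estimate of the readily-releasable pool (Nq).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..trains import TrainRecording

__all__ = ["ReleaseModelSpec", "simulate_depression_train"]


@dataclass(frozen=True)
class ReleaseModelSpec:
    """Parameters of the depletion–replenishment train model."""

    N: float = 100.0  # release sites
    q: float = 1.0  # quantal amplitude (a.u.)
    p: float = 0.5  # release fraction per pulse
    k_rep: float = 0.0  # replenishment rate constant, 1/s
    n_pulses: int = 100
    frequency: float = 20.0  # Hz
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.p <= 1:
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.k_rep < 0:
            raise ValueError(f"k_rep must be >= 0, got {self.k_rep}")
        if not self.N > 0:
            raise ValueError(f"N must be > 0, got {self.N}")
        if not self.q > 0:
            raise ValueError(f"q must be > 0, got {self.q}")
        if self.n_pulses < 1:
            raise ValueError(f"n_pulses must be >= 1, got {self.n_pulses}")
        if not self.frequency > 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")


def pool_fixed_point(spec: ReleaseModelSpec) -> float:
    """Steady-state occupied pool of the between-pulse update map."""
    r = 1.0 - np.exp(-spec.k_rep / spec.frequency)
    # P* = P*(1-p)(1-r) + N r  =>  P* = N r / (1 - (1-p)(1-r))
    denom = 1.0 - (1.0 - spec.p) * (1.0 - r)
    return float(spec.N * r / denom) if denom > 0 else float(spec.N)


def simulate_depression_train(spec: ReleaseModelSpec) -> TrainRecording:
    """Simulate per-pulse response amplitudes for a stimulus train."""
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.frequency
    recovery = 1.0 - np.exp(-dt * spec.k_rep)
    pool = spec.N
    amps = np.empty(spec.n_pulses)
    for i in range(spec.n_pulses):
        amps[i] = spec.q * spec.p * pool
        survived = pool * (1.0 - spec.p)
        pool = survived + (spec.N - survived) * recovery
    if spec.noise_sd > 0:
        amps = amps + rng.normal(0.0, spec.noise_sd, size=spec.n_pulses)
    times = np.arange(spec.n_pulses) * dt
    return TrainRecording(
        stimulus_times=times,
        amplitudes=amps,
        metadata={
            "frequency_hz": spec.frequency,
            "n_pulses": spec.n_pulses,
            "model": "depletion-replenishment",
            "N": spec.N, "q": spec.q, "p": spec.p, "k_rep": spec.k_rep,
            "noise_sd": spec.noise_sd, "seed": spec.seed, "rng": "numpy PCG64",
        },
    )
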
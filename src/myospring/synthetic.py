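"""Synthetic fixtures: noisy force surfaces, stretch protocols, schedules.

These generators emulate the inputs the models are meant to consume so
that every fitting and simulation path is testable without external data:

* :func:`gen_force_surface` — an isometric force-length-frequency surface
  sampled on a grid with additive Gaussian observation noise, standing in
  for digitized experimental force tables;
* :func:`gen_stimulus` — a classic ramp-and-hold(-and-release) stretch
  protocol with an analytically consistent length rate, the standard
  stimulus used to characterize spindle afferents;
* :func:`gen_activation_schedule` — piecewise-constant antagonist
  activation schedules driving saccade-style plant simulations.

All randomness flows through explicit integer seeds; generators never
touch global RNG state.  Noisy force values are NOT clipped at zero —
downstream fitting must cope with slightly negative samples, as it would
with real digitization error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .spindle import StimulusProfile

__all__ = [
    "SurfaceSpec",
    "ProtocolSpec",
    "ActivationSchedule",
    "gen_force_surface",
    "gen_stimulus",
    "gen_activation_schedule",
]


@dataclass(frozen=True)
class SurfaceSpec:
    """Sampling grid, noise level (Fo units) and seed for a force surface."""

    alphas: tuple
    Ls: tuple
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))
        object.__setattr__(self, "Ls", tuple(float(x) for x in self.Ls))


@dataclass(frozen=True)
class ProtocolSpec:
    """Ramp-and-hold stretch protocol parameters.

    Length starts at ``baseline``, ramps up at ``ramp_rate`` (length/s) for
    ``ramp_duration`` s, holds for ``hold_duration`` s, then releases at
    ``release_rate`` (>= 0; 0 disables the release) back toward baseline.
    ``gamma`` is a constant dynamic fusimotor drive (pps).
    """

    baseline: float = 2.0
    ramp_rate: float = 0.5
    ramp_duration: float = 1.0
    hold_duration: float = 2.0
    release_rate: float = 0.5
    gamma: float = 0.0
    sample_rate: float = 1000.0
    lead_in: float = 0.5

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if min(self.ramp_duration, self.hold_duration, self.lead_in) < 0:
            raise ValueError("durations must be nonnegative")
        if self.release_rate < 0 or self.ramp_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


def gen_force_surface(model: Callable, spec: SurfaceSpec) -> pd.DataFrame:
    """Sample ``model(alpha, L)`` on the spec grid with Gaussian noise.

    ``model`` is any callable of (alpha_pps, L_norm) returning normalized
    force, e.g. ``EvaluationModel().total_isometric`` or an active-force
    method.  Returns a DataFrame with columns (alpha_pps, L_norm, F_norm);
    rows iterate L fastest.  Identical specs produce identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    A, L = np.meshgrid(spec.alphas, spec.Ls, indexing="ij")
    F = np.asarray(model(A, L), dtype=float)
    if spec.noise_sd > 0:
        F = F + rng.normal(0.0, spec.noise_sd, size=F.shape)
    return pd.DataFrame(
        {"alpha_pps": A.ravel(), "L_norm": L.ravel(), "F_norm": F.ravel()}
    )


def gen_stimulus(spec: ProtocolSpec) -> StimulusProfile:
    """Trapezoidal ramp-and-hold length profile with analytic length rate.

    The profile is sampled at ``spec.sample_rate`` with corner times
    included exactly; Ldot is the analytic piecewise-constant rate (so it
    matches finite differences of L to O(dt^2) away from corners).
    """
    rise = spec.ramp_rate * spec.ramp_duration
    t1 = spec.lead_in
    t2 = t1 + spec.ramp_duration
    t3 = t2 + spec.hold_duration
    release_dur = rise / spec.release_rate if spec.release_rate > 0 else 0.0
    t4 = t3 + release_dur
    t_end = t4 + spec.lead_in
    dt = 1.0 / spec.sample_rate
    t = np.unique(np.concatenate([np.arange(0.0, t_end + dt / 2, dt), [t1, t2, t3, t4]]))

    L = np.full_like(t, spec.baseline)
    Ld = np.zeros_like(t)
    ramp = (t >= t1) & (t < t2)
    L[ramp] = spec.baseline + spec.ramp_rate * (t[ramp] - t1)
    Ld[ramp] = spec.ramp_rate
    hold = (t >= t2) & (t < t3)
    L[hold] = spec.baseline + rise
    if spec.release_rate > 0:
        rel = (t >= t3) & (t < t4)
        L[rel] = spec.baseline + rise - spec.release_rate * (t[rel] - t3)
        Ld[rel] = -spec.release_rate
    else:
        L[t >= t3] = spec.baseline + rise
    return StimulusProfile(
        t=t, L=L, Ldot=Ld, gamma=spec.gamma, consistency_rtol=None
    )


@dataclass(frozen=True)
class ActivationSchedule:
    """Piecewise-constant antagonist activation schedule (a1, a2)(t).

    ``times`` are switch instants (strictly increasing); ``levels`` has one
    (a1, a2) pair more than ``times`` — the leading pair is the baseline
    before the first switch.
    """

    times: tuple
    levels: tuple

    def __post_init__(self) -> None:
        times = tuple(float(x) for x in self.times)
        levels = tuple((float(a), float(b)) for a, b in self.levels)
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("switch times must be strictly increasing")
        if len(levels) != len(times) + 1:
            raise ValueError("need exactly len(times) + 1 activation pairs")
        for a, b in levels:
            if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
                raise ValueError("activations must lie in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "levels", levels)

    def __call__(self, t: float) -> tuple:
        i = int(np.searchsorted(self.times, t, side="right"))
        return self.levels[i]

    @property
    def n_switches(self) -> int:
        return len(self.times)


def gen_activation_schedule(
    kind: str,
    levels: Sequence,
    times: Sequence,
    baseline: tuple = (0.0, 0.0),
) -> ActivationSchedule:
    """Build a step or pulse activation schedule.

    ``kind="step"``: one switch per entry of ``times``, to the matching
    entry of ``levels``.  ``kind="pulse"``: each (on, off) pair in ``times``
    applies the matching level then returns to ``baseline``.  An empty
    schedule yields the constant baseline.
    """
    if kind == "step":
        if len(levels) != len(times):
            raise ValueError("step schedule needs one level per switch time")
        return ActivationSchedule(tuple(times), (baseline, *levels))
    if kind == "pulse":
        if len(levels) != len(times):
            raise ValueError("pulse schedule needs one level per (on, off) pair")
        switch_times: list = []
        pairs: list = [baseline]
        for level, (on, off) in zip(levels, times):
            if off <= on:
                raise ValueError("pulse off time must exceed on time")
            if switch_times and on < switch_times[-1]:
                raise ValueError("pulses overlap")
            switch_times += [on, off]
            pairs += [tuple(level), baseline]
        return ActivationSchedule(tuple(switch_times), tuple(pairs))
    raise ValueError(f"unknown schedule kind {kind!r}")
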
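"""Hybrid dynamical models of the muscle-spindle Ia and II afferents.

Both afferents are modelled as first-order linear filters whose gain and
eigenvalue are reset by the sign regime of the muscle length rate — a
hybrid dynamical system with a continuous flow and discrete jumps:

Spindle-Ia (primary, velocity-sensitive):

    flow:   x' = p * (KL * L - x),   p' = 0, KL' = 0
    output: y  = sat0(x + Kgamma * gamma + KLdot * Ldot)
    jumps:  Ldot < 0 (shortening)  -> KL = 0,     p = p_fast
            Ldot > 0 (lengthening) -> KL = KL_on, p = p_fast
            Ldot = 0 (static)      -> KL = 0,     p = p_slow
            x is unchanged at every jump.

Spindle-II (secondary, length-sensitive) replaces the gain switch with a
binary path switch xi in {0, 1}; xi = 0 freezes the filter state entirely
and routes the static length pathway straight to the output:

    flow:   x' = p * xi * (KL * L - x)
    output: y  = sat0(x + Kgamma*gamma + KLdot*Ldot + (1 - xi)*KL*(L - Lbar))
    jumps:  shortening -> xi = 0, p = p_fast; lengthening -> xi = 1,
            p = p_fast; static -> xi = 0, p = p_slow; x unchanged.

The inputs L, Ldot and the dynamic fusimotor drive gamma (pps) are supplied
as a sampled :class:`StimulusProfile` (piecewise-linear between samples).
The exact condition "Ldot = 0" is a measure-zero event for sampled signals,
so a configurable velocity deadband ``eps_v`` (default 1e-6 length-units/s)
defines the static regime; the deadband also makes the three regimes
mutually exclusive, ruling out Zeno behaviour together with the one-shot
jump conditions.

Between regime changes the flow is a scalar linear ODE driven by a
piecewise-linear input, which the simulator integrates exactly (first-order
hold exponential stepping); no tolerance-dependent ODE solver is involved.
Spindle length units are taken as supplied by the caller — the length
offset Lbar = 2.5 of the II model implies a normalization different from
the muscle model's L/Lo, and no implicit rescaling is applied.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SpindleIaParams",
    "SpindleIIParams",
    "HybridStateIa",
    "HybridStateII",
    "StimulusProfile",
    "AfferentTrace",
    "Regime",
    "DEFAULT_EPS_V",
    "sat0",
    "classify_regime",
    "jump_ia",
    "flow_ia",
    "output_ia",
    "simulate_ia",
    "jump_ii",
    "flow_ii",
    "output_ii",
    "simulate_ii",
]

DEFAULT_EPS_V = 1e-6


def sat0(v: float) -> float:
    """Zero saturation: negative values clip to 0 (afferents cannot fire negatively)."""
    return v if v > 0.0 else 0.0


class Regime(enum.Enum):
    """Sign regime of the length rate, with a deadband around zero."""

    SHORTENING = "shortening"
    LENGTHENING = "lengthening"
    STATIC = "static"


def classify_regime(Ldot: float, eps_v: float = DEFAULT_EPS_V) -> Regime:
    """Classify Ldot into shortening / lengthening / static with deadband eps_v."""
    if eps_v <= 0:
        raise ValueError("eps_v must be positive")
    if Ldot < -eps_v:
        return Regime.SHORTENING
    if Ldot > eps_v:
        return Regime.LENGTHENING
    return Regime.STATIC


@dataclass(frozen=True)
class SpindleIaParams:
    """Gains and eigenvalues of the Spindle-Ia hybrid filter."""

    p_fast: float = 85.0
    p_slow: float = 3.858
    KL_on: float = 7.15
    KLdot: float = 5.15
    Kgamma: float = 0.3514

    def __post_init__(self) -> None:
        if not self.p_fast > self.p_slow > 0:
            raise ValueError("need p_fast > p_slow > 0")
        if min(self.KL_on, self.KLdot, self.Kgamma) < 0:
            raise ValueError("gains must be nonnegative")


@dataclass(frozen=True)
class SpindleIIParams:
    """Gains, eigenvalues and length offset of the Spindle-II hybrid filter."""

    p_fast: float = 85.0
    p_slow: float = 2.858
    KL: float = 4.334
    KLdot: float = 0.9184
    Kgamma: float = 0.343
    Lbar: float = 2.5

    def __post_init__(self) -> None:
        if not self.p_fast > self.p_slow > 0:
            raise ValueError("need p_fast > p_slow > 0")
        if min(self.KL, self.KLdot, self.Kgamma) < 0:
            raise ValueError("gains must be nonnegative")


@dataclass(frozen=True)
class HybridStateIa:
    """Spindle-Ia mode variables: filter state x, length gain KL, eigenvalue p."""

    x: float
    KL: float
    p: float


@dataclass(frozen=True)
class HybridStateII:
    """Spindle-II mode variables: filter state x, path switch xi, eigenvalue p."""

    x: float
    xi: int
    p: float

    def __post_init__(self) -> None:
        if self.xi not in (0, 1):
            raise ValueError("xi must be 0 or 1")


def jump_ia(
    state: HybridStateIa, regime: Regime, params: SpindleIaParams = SpindleIaParams()
) -> HybridStateIa:
    """Apply the Ia jump map for ``regime``; x is continuous across the jump."""
    if regime is Regime.SHORTENING:
        return replace(state, KL=0.0, p=params.p_fast)
    if regime is Regime.LENGTHENING:
        return replace(state, KL=params.KL_on, p=params.p_fast)
    return replace(state, KL=0.0, p=params.p_slow)


def flow_ia(state: HybridStateIa, L: float) -> float:
    """Ia flow vector field dx/dt = p * (KL * L - x)."""
    return state.p * (state.KL * L - state.x)


def output_ia(
    state: HybridStateIa,
    Ldot: float,
    gamma: float,
    params: SpindleIaParams = SpindleIaParams(),
) -> float:
    """Ia afferent rate y = sat0(x + Kgamma*gamma + KLdot*Ldot)."""
    if gamma < 0:
        raise ValueError("gamma drive must be nonnegative")
    return sat0(state.x + params.Kgamma * gamma + params.KLdot * Ldot)


def jump_ii(
    state: HybridStateII, regime: Regime, params: SpindleIIParams = SpindleIIParams()
) -> HybridStateII:
    """Apply the II jump map for ``regime``; x is continuous across the jump."""
    if regime is Regime.SHORTENING:
        return replace(state, xi=0, p=params.p_fast)
    if regime is Regime.LENGTHENING:
        return replace(state, xi=1, p=params.p_fast)
    return replace(state, xi=0, p=params.p_slow)


def flow_ii(
    state: HybridStateII, L: float, params: SpindleIIParams = SpindleIIParams()
) -> float:
    """II flow vector field dx/dt = p * xi * (KL * L - x); xi = 0 freezes x."""
    return state.p * state.xi * (params.KL * L - state.x)


def output_ii(
    state: HybridStateII,
    L: float,
    Ldot: float,
    gamma: float,
    params: SpindleIIParams = SpindleIIParams(),
) -> float:
    """II afferent rate; the static length pathway is gated in only when xi = 0."""
    if gamma < 0:
        raise ValueError("gamma drive must be nonnegative")
    static_path = (1 - state.xi) * params.KL * (L - params.Lbar)
    return sat0(state.x + params.Kgamma * gamma + params.KLdot * Ldot + static_path)


@dataclass(frozen=True)
class StimulusProfile:
    """Sampled stretch stimulus: time, length, length rate and fusimotor drive.

    Signals are treated as piecewise linear between samples.  ``t`` must be
    strictly increasing.  If ``Ldot`` is omitted it is computed by centered
    finite differences of ``L``; if both are given, their consistency is
    checked to ``consistency_rtol`` (relative to the peak rate) unless the
    tolerance is set to ``None``.
    """

    t: np.ndarray
    L: np.ndarray
    Ldot: np.ndarray | None = None
    gamma: np.ndarray | float = 0.0
    consistency_rtol: float | None = 0.05

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        L = np.asarray(self.L, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("need at least two samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        if L.shape != t.shape:
            raise ValueError("L must match t in shape")
        if self.Ldot is None:
            ld = np.gradient(L, t)
        else:
            ld = np.asarray(self.Ldot, dtype=float)
            if ld.shape != t.shape:
                raise ValueError("Ldot must match t in shape")
            if self.consistency_rtol is not None:
                fd = np.gradient(L, t)
                tol = self.consistency_rtol * np.max(np.abs(ld)) + 1e-9 * max(
                    1.0, float(np.max(np.abs(L)))
                )
                # interior points only (centered differences are O(dt^2) there);
                # isolated excursions at rate discontinuities are expected, so
                # only a systematic disagreement is an error
                bad = np.abs(fd[1:-1] - ld[1:-1]) > tol
                if np.mean(bad) > 0.02:
                    raise ValueError("Ldot is inconsistent with finite differences of L")
        g = np.asarray(self.gamma, dtype=float)
        if g.ndim == 0:
            g = np.full_like(t, float(g))
        elif g.shape != t.shape:
            raise ValueError("gamma must be scalar or match t in shape")
        if np.any(g < 0):
            raise ValueError("gamma drive must be nonnegative")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "L", L)
        object.__setattr__(self, "Ldot", ld)
        object.__setattr__(self, "gamma", g)


@dataclass(frozen=True)
class AfferentTrace:
    """Simulated afferent response: state x, output y, regime tag, jump log."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    mode: tuple  # regime value string per sample
    jumps: tuple  # (time, regime value string) per jump

    def __len__(self) -> int:
        return self.t.size


def _refine_segments(profile: StimulusProfile, eps_v: float):
    """Subdivide the sample grid at deadband crossings of the linear Ldot.

    Yields a refined strictly increasing time grid with L, Ldot, gamma
    interpolated, such that the regime is constant within each interval.
    """
    t, L, ld, g = profile.t, profile.L, profile.Ldot, profile.gamma
    times = [t[0]]
    for i in range(t.size - 1):
        t0, t1 = t[i], t[i + 1]
        v0, v1 = ld[i], ld[i + 1]
        cuts = []
        for thr in (-eps_v, eps_v):
            if (v0 - thr) * (v1 - thr) < 0:
                cuts.append(t0 + (thr - v0) * (t1 - t0) / (v1 - v0))
        for tc in sorted(cuts):
            if tc > times[-1] + 1e-15:
                times.append(tc)
        if t1 > times[-1] + 1e-15:
            times.append(t1)
    tr = np.asarray(times)
    return tr, np.interp(tr, t, L), np.interp(tr, t, ld), np.interp(tr, t, g)


def _exact_step(x0, p, gain_L, L0, L1, h):
    """Exact step of x' = p*(gain_L*L(t) - x) with L linear from L0 to L1 over h."""
    if h <= 0:
        return x0
    b = (L1 - L0) / h
    # particular solution: gain_L*L(t) - gain_L*b/p; homogeneous decay of the rest
    drift = gain_L * b / p if p > 0 else 0.0
    xp0 = gain_L * L0 - drift
    xp1 = gain_L * L1 - drift
    return xp1 + (x0 - xp0) * math.exp(-p * h)


def _simulate(kind: str, params, profile: StimulusProfile, x0, eps_v) -> AfferentTrace:
    tr, Lr, ldr, gr = _refine_segments(profile, eps_v)
    n = tr.size
    xs = np.empty(n)
    ys = np.empty(n)
    modes = []
    jumps = []

    def seg_regime(i):
        # evaluate at the interval midpoint: regime is constant there
        vmid = 0.5 * (ldr[i] + ldr[i + 1])
        return classify_regime(vmid, eps_v)

    regime0 = classify_regime(ldr[0], eps_v)
    if kind == "ia":
        state = jump_ia(HybridStateIa(0.0, 0.0, 1.0), regime0, params)
        if x0 is None:
            # flow equilibrium of the initial mode (0 when the length gain is off)
            x_init = state.KL * Lr[0]
        else:
            x_init = float(x0)
        state = replace(state, x=x_init)
        out = lambda s, i: output_ia(s, ldr[i], gr[i], params)
        gain = lambda s: s.KL
        do_jump = lambda s, r: jump_ia(s, r, params)
        frozen = lambda s: False
    else:
        state = jump_ii(HybridStateII(0.0, 0, 1.0), regime0, params)
        if x0 is None:
            x_init = params.KL * Lr[0] if state.xi else 0.0
        else:
            x_init = float(x0)
        state = replace(state, x=x_init)
        out = lambda s, i: output_ii(s, Lr[i], ldr[i], gr[i], params)
        gain = lambda s: params.KL * s.xi
        do_jump = lambda s, r: jump_ii(s, r, params)
        frozen = lambda s: s.xi == 0

    current = regime0
    jumps.append((float(tr[0]), current.value))
    xs[0] = state.x
    ys[0] = out(state, 0)
    modes.append(current.value)
    for i in range(n - 1):
        r = seg_regime(i)
        if r is not current:
            state = do_jump(state, r)  # x unchanged by the jump map
            current = r
            jumps.append((float(tr[i]), r.value))
        h = tr[i + 1] - tr[i]
        if frozen(state):
            x_new = state.x
        else:
            x_new = _exact_step(state.x, state.p, gain(state), Lr[i], Lr[i + 1], h)
        state = replace(state, x=x_new)
        xs[i + 1] = state.x
        ys[i + 1] = out(state, i + 1)
        modes.append(current.value)
    return AfferentTrace(t=tr, x=xs, y=ys, mode=tuple(modes), jumps=tuple(jumps))


def simulate_ia(
    params: SpindleIaParams = SpindleIaParams(),
    profile: StimulusProfile | None = None,
    x0: float | None = None,
    eps_v: float = DEFAULT_EPS_V,
) -> AfferentTrace:
    """Event-driven simulation of the Spindle-Ia hybrid system.

    Flows between deadband crossings of Ldot with exactly one jump applied
    per regime change; the scalar linear flow is integrated exactly
    (first-order-hold exponential stepping).  ``x0`` defaults to the flow
    equilibrium of the initial regime.
    """
    if profile is None:
        raise ValueError("a StimulusProfile is required")
    if x0 is not None and x0 < 0:
        raise ValueError("x0 must be nonnegative")
    return _simulate("ia", params, profile, x0, eps_v)


def simulate_ii(
    params: SpindleIIParams = SpindleIIParams(),
    profile: StimulusProfile | None = None,
    x0: float | None = None,
    eps_v: float = DEFAULT_EPS_V,
) -> AfferentTrace:
    """Event-driven simulation of the Spindle-II hybrid system (see simulate_ia)."""
    if profile is None:
        raise ValueError("a StimulusProfile is required")
    if x0 is not None and x0 < 0:
        raise ValueError("x0 must be nonnegative")
    return _simulate("ii", params, profile, x0, eps_v)
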
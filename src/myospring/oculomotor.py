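"""Horizontal oculomotor plant actuated by two antagonist muscle springs.

The eyeball is a damped rotational inertia driven by the torque of two
antagonist muscles, each described by the controllable nonlinear spring
model:

    theta' = omega
    J omega' = -beta omega + R*F1(a1, L1) - R*F2(a2, L2),
    L1 = L10 - R*theta,   L2 = L20 + R*theta

where theta is the angular displacement from the sagittal plane, R the
eyeball radius, and Fi the zero-saturated spring force of muscle i at its
current length and alpha-motoneuron rate.  Activations are supplied
normalized in [0, 1] and mapped to firing rates by x120 pps before
entering the muscle model.

The forward map (a1, a2) -> torque is surjective onto its range but not
injective: many co-contraction levels produce the same torque at different
joint stiffness, which :func:`find_isotorque_pairs` demonstrates
constructively and :func:`joint_stiffness` quantifies.

Each muscle carries a spindle pair (Ia, II) whose inputs are the muscle
length and rate mapped through an affine :class:`SpindleCoupling` (the
spindle models operate on a different length normalization — their static
length offset sits at 2.5 — so the plant's lengths around 0.5 Lo are
scaled into the spindle's working range).  The static spindle-II pathway
is invertible, which :func:`reconstruct_angle` uses to recover theta from
afferent rates.

By default the muscles use a Control Model regenerated from the Evaluation
Model via the fitting pipeline rather than the printed coefficient table:
the printed stiffness coefficients are numerically unreliable above ~50
pps (see :mod:`myospring.control`), which is exactly the range saccade
simulations exercise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .control import ControlModel, fit_control_model
from .evaluation import ModelDomainWarning
from .spindle import (
    SpindleIaParams,
    SpindleIIParams,
    StimulusProfile,
    simulate_ia,
    simulate_ii,
)
from .synthetic import ActivationSchedule

__all__ = [
    "EyePlantParams",
    "EyeState",
    "ActivationPair",
    "SpindleCoupling",
    "EyeTrajectory",
    "default_muscle_model",
    "muscle_lengths",
    "torque",
    "dynamics",
    "simulate",
    "equilibrium_angle",
    "joint_stiffness",
    "find_isotorque_pairs",
    "reconstruct_angle",
]

PPS_PER_UNIT_ACTIVATION = 120.0


@lru_cache(maxsize=1)
def default_muscle_model() -> ControlModel:
    """Control Model regenerated from the default Evaluation Model (cached)."""
    model, _, _ = fit_control_model()
    return model


@dataclass(frozen=True)
class ActivationPair:
    """Normalized antagonist activations (a1, a2) in [0, 1]."""

    a1: float = 0.7
    a2: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.a1 <= 1.0 and 0.0 <= self.a2 <= 1.0):
            raise ValueError("activations must lie in [0, 1]")

    @property
    def pps(self) -> tuple:
        return (self.a1 * PPS_PER_UNIT_ACTIVATION, self.a2 * PPS_PER_UNIT_ACTIVATION)


@dataclass(frozen=True)
class SpindleCoupling:
    """Affine map from plant muscle length (Lo units) to spindle length units.

    L_spindle = scale * L_muscle + offset; rates scale by ``scale``.  The
    defaults put the plant's neutral length 0.5 at spindle length 3.0,
    comfortably above the spindle-II static offset 2.5 so the static
    pathway stays observable over the plant's range of motion.
    """

    scale: float = 4.0
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def to_spindle(self, L_muscle):
        return self.scale * np.asarray(L_muscle, float) + self.offset

    def to_muscle(self, L_spindle):
        return (np.asarray(L_spindle, float) - self.offset) / self.scale


@dataclass(frozen=True)
class EyePlantParams:
    """Oculomotor plant constants (adimensional J and R; damping beta)."""

    J: float = 1.0
    R: float = 1.0
    beta: float = 20.0
    L10: float = 0.5
    L20: float = 0.5
    muscle: ControlModel = field(default_factory=default_muscle_model)
    coupling: SpindleCoupling = field(default_factory=SpindleCoupling)

    def __post_init__(self) -> None:
        if self.J <= 0 or self.R <= 0 or self.beta < 0:
            raise ValueError("need J > 0, R > 0, beta >= 0")
        if min(self.L10, self.L20) <= 0:
            raise ValueError("neutral lengths must be positive")

    @property
    def theta_range(self) -> tuple:
        """Admissible angles keeping both muscle lengths >= 0.4 Lo."""
        return (-(self.L20 - 0.4) / self.R, (self.L10 - 0.4) / self.R)


@dataclass(frozen=True)
class EyeState:
    """Eye plant state: angle (rad) and angular velocity (rad/s)."""

    theta: float = 0.0
    omega: float = 0.0


@dataclass(frozen=True)
class EyeTrajectory:
    """Simulated plant trajectory with muscle and afferent signals."""

    t: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    L1: np.ndarray
    L2: np.ndarray
    F1: np.ndarray
    F2: np.ndarray
    y_ia_1: np.ndarray | None = None
    y_ii_1: np.ndarray | None = None
    y_ia_2: np.ndarray | None = None
    y_ii_2: np.ndarray | None = None


def muscle_lengths(theta: float, params: EyePlantParams) -> tuple:
    """Antagonist lengths L1 = L10 - R*theta, L2 = L20 + R*theta."""
    L1 = params.L10 - params.R * theta
    L2 = params.L20 + params.R * theta
    if L1 <= 0 or L2 <= 0:
        raise ValueError(f"nonpositive muscle length at theta={theta}")
    return (L1, L2)


def torque(a1: float, a2: float, theta: float, params: EyePlantParams) -> float:
    """Net torque R*F1 - R*F2 of the (zero-saturated) muscle springs."""
    L1, L2 = muscle_lengths(theta, params)
    p1, p2 = ActivationPair(a1, a2).pps
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ModelDomainWarning)
        F1 = params.muscle.iso_force(p1, L1)
        F2 = params.muscle.iso_force(p2, L2)
    return params.R * (F1 - F2)


def dynamics(state: EyeState, a1: float, a2: float, params: EyePlantParams) -> tuple:
    """Plant vector field (dtheta/dt, domega/dt)."""
    tau = torque(a1, a2, state.theta, params)
    return (state.omega, (-params.beta * state.omega + tau) / params.J)


def simulate(
    params: EyePlantParams,
    schedule: ActivationSchedule,
    t_span: tuple = (0.0, 10.0),
    *,
    state0: EyeState = EyeState(),
    n_samples: int = 1000,
    with_spindles: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> EyeTrajectory:
    """Integrate the plant under a piecewise-constant activation schedule.

    Integration restarts at each schedule switch so activation steps are
    sharp.  Muscle lengths leaving the spring model's validity box raise a
    warning naming the first offending time.  When ``with_spindles`` is on,
    the afferent responses of both muscles (through the spindle coupling)
    are simulated along the trajectory and logged.
    """
    t0, t1 = map(float, t_span)
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    breaks = [t for t in schedule.times if t0 < t < t1]
    edges = [t0, *breaks, t1]
    t_out = np.linspace(t0, t1, n_samples)
    thetas = np.empty_like(t_out)
    omegas = np.empty_like(t_out)
    y0 = [state0.theta, state0.omega]
    filled = 0
    for lo, hi in zip(edges, edges[1:]):
        a1, a2 = schedule(0.5 * (lo + hi))

        def rhs(t, y):
            s = EyeState(theta=y[0], omega=y[1])
            return dynamics(s, a1, a2, params)

        mask = (t_out >= lo) & (t_out <= hi)
        t_eval = t_out[mask]
        sol = solve_ivp(
            rhs, (lo, hi), y0, t_eval=t_eval, rtol=rtol, atol=atol, method="RK45"
        )
        if not sol.success:
            raise RuntimeError(f"plant integration failed on [{lo}, {hi}]: {sol.message}")
        thetas[filled : filled + t_eval.size] = sol.y[0]
        omegas[filled : filled + t_eval.size] = sol.y[1]
        filled += t_eval.size
        # restart from the interval's right endpoint
        end = solve_ivp(rhs, (lo, hi), y0, rtol=rtol, atol=atol, method="RK45")
        y0 = [end.y[0][-1], end.y[1][-1]]

    lo_th, hi_th = params.theta_range
    out_of_box = (thetas < lo_th) | (thetas > hi_th)
    if np.any(out_of_box):
        t_first = t_out[np.argmax(out_of_box)]
        warnings.warn(
            f"muscle lengths left the validity box at t={t_first:.4f} s",
            ModelDomainWarning,
            stacklevel=2,
        )

    L1 = params.L10 - params.R * thetas
    L2 = params.L20 + params.R * thetas
    pps = np.array([ActivationPair(*schedule(t)).pps for t in t_out])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ModelDomainWarning)
        F1 = np.array([params.muscle.iso_force(p, ell) for p, ell in zip(pps[:, 0], L1)])
        F2 = np.array([params.muscle.iso_force(p, ell) for p, ell in zip(pps[:, 1], L2)])

    traj = EyeTrajectory(t=t_out, theta=thetas, omega=omegas, L1=L1, L2=L2, F1=F1, F2=F2)
    if not with_spindles:
        return traj

    c = params.coupling
    afferents = {}
    for name, L, sgn in (("1", L1, -1.0), ("2", L2, +1.0)):
        prof = StimulusProfile(
            t=t_out,
            L=c.to_spindle(L),
            Ldot=sgn * params.R * omegas * c.scale,
            gamma=0.0,
            consistency_rtol=None,
        )
        tr_ia = simulate_ia(SpindleIaParams(), prof)
        tr_ii = simulate_ii(SpindleIIParams(), prof)
        afferents[f"y_ia_{name}"] = np.interp(t_out, tr_ia.t, tr_ia.y)
        afferents[f"y_ii_{name}"] = np.interp(t_out, tr_ii.t, tr_ii.y)
    return EyeTrajectory(
        t=t_out, theta=thetas, omega=omegas, L1=L1, L2=L2, F1=F1, F2=F2, **afferents
    )


def equilibrium_angle(
    a1: float,
    a2: float,
    params: EyePlantParams,
    *,
    tol: float = 1e-10,
) -> float:
    """Resting angle reached from theta = 0 under constant activations.

    Walks outward from 0 in the direction of the initial torque and locates
    the first zero of tau by bracketing + bisection.  Because the muscle
    forces saturate at zero, tau can reach zero at the edge of a slack
    plateau rather than crossing sign; the bisection then resolves the
    plateau boundary, which is where the damped dynamics comes to rest.
    """
    lo_th, hi_th = params.theta_range
    tau0 = torque(a1, a2, 0.0, params)
    if tau0 == 0.0:
        return 0.0
    direction = 1.0 if tau0 > 0 else -1.0
    edge = hi_th if direction > 0 else lo_th
    grid = np.linspace(0.0, edge, 200)
    taus = np.array([torque(a1, a2, th, params) for th in grid])
    sgn0 = np.sign(tau0)
    stop = np.nonzero(np.sign(taus) != sgn0)[0]  # first sign change or plateau entry
    if stop.size == 0:
        raise ValueError(
            f"torque does not vanish on the admissible range for a=({a1}, {a2})"
        )
    i = stop[0]
    lo, hi = grid[i - 1], grid[i]
    tau_hi = taus[i]
    if tau_hi * tau0 < 0:
        return float(brentq(lambda th: torque(a1, a2, th, params), lo, hi, xtol=tol))
    # plateau boundary: bisect on the predicate sign(tau) == sign(tau0)
    while abs(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        if np.sign(torque(a1, a2, mid, params)) == sgn0:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))


def joint_stiffness(
    a1: float, a2: float, theta: float, params: EyePlantParams, *, step: float = 1e-4
) -> float:
    """Rotational stiffness -d(tau)/d(theta) by central finite difference."""
    tp = torque(a1, a2, theta + step, params)
    tm = torque(a1, a2, theta - step, params)
    return -(tp - tm) / (2.0 * step)


def find_isotorque_pairs(
    tau_target: float,
    theta: float,
    params: EyePlantParams,
    n: int = 5,
    *,
    tol: float = 1e-12,
) -> list:
    """Find ``n`` distinct activation pairs producing the same torque.

    Sweeps the antagonist activation a2 over widely spaced levels (so the
    returned pairs span genuinely different co-contraction) and solves for
    the agonist a1 by bracketing the torque residual; demonstrates that
    the activation-to-torque map is surjective onto its range but not
    injective.  Raises if fewer than ``n`` pairs are attainable.
    """
    def solve_a1(a2: float):
        f = lambda a1: torque(a1, a2, theta, params) - tau_target
        f0, f1 = f(0.0), f(1.0)
        if f0 == 0.0:
            return 0.0
        if f0 * f1 < 0:
            return brentq(f, 0.0, 1.0, xtol=1e-14)
        return None

    # largest antagonist level at which the target is still attainable
    a2_max = None
    for a2 in np.linspace(1.0, 0.0, 101):
        if solve_a1(float(a2)) is not None:
            a2_max = float(a2)
            break
    if a2_max is None:
        raise ValueError(f"torque {tau_target} is unattainable at theta={theta}")
    pairs: list = []
    candidates = list(np.linspace(0.0, a2_max, n)) + list(np.linspace(0.0, a2_max, 101))
    for a2 in candidates:
        a1_sol = solve_a1(float(a2))
        if a1_sol is None or abs(torque(a1_sol, float(a2), theta, params) - tau_target) > 1e-8:
            continue
        pair = ActivationPair(float(a1_sol), float(a2))
        if all(abs(pair.a2 - p.a2) > 1e-6 or abs(pair.a1 - p.a1) > 1e-6 for p in pairs):
            pairs.append(pair)
        if len(pairs) == n:
            return pairs
    raise ValueError(
        f"only {len(pairs)} activation pairs reach torque {tau_target} at theta={theta}"
    )


def reconstruct_angle(
    y_ia_1: float,
    y_ii_1: float,
    y_ia_2: float,
    y_ii_2: float,
    params: EyePlantParams,
    *,
    gamma: float = 0.0,
    spindle_ii: SpindleIIParams = SpindleIIParams(),
    true_theta: float | None = None,
) -> tuple:
    """Recover theta from static spindle-II rates of the two muscles.

    In a static hold the spindle-II output is the affine static pathway
    y = KL*(L_sp - Lbar) + Kgamma*gamma, inverted per muscle and mapped
    back through the spindle coupling; theta = (L2 - L1) / (2 R) assuming
    equal neutral lengths.  Returns (theta_hat, observable, residual);
    ``observable`` is False (and theta_hat NaN) when either output sits in
    the saturated-zero region, where the inversion is undefined.  The Ia
    rates are accepted for interface symmetry; in a static hold they carry
    no additional length information (their state has adapted away).
    """
    if abs(params.L10 - params.L20) > 1e-12:
        raise ValueError("angle reconstruction assumes equal neutral lengths")
    if y_ii_1 <= 0.0 or y_ii_2 <= 0.0:
        return (float("nan"), False, None)
    c = params.coupling
    Lsp = [
        spindle_ii.Lbar + (y - spindle_ii.Kgamma * gamma) / spindle_ii.KL
        for y in (y_ii_1, y_ii_2)
    ]
    L1, L2 = (float(c.to_muscle(v)) for v in Lsp)
    theta_hat = (L2 - L1) / (2.0 * params.R)
    residual = None if true_theta is None else theta_hat - true_theta
    return (theta_hat, True, residual)
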
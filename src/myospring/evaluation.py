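"""Intermediate isometric force model ("Evaluation Model").

The total isometric force of a skeletal muscle is modelled as the sum of an
active and a passive component, saturated at zero:

    F_ISO(alpha, L) = max(0, FL(alpha, L) + Fp(L))

The active component is a Gaussian in normalized length L whose amplitude
A, mean mu and width sigma all depend on the alpha-motoneuron firing rate
alpha (pps, in [0, 120]):

    FL = A(alpha) * exp(-((L - mu(alpha)) / sigma(alpha))**2)
    A     = (c11 a^2 + c12 a + c13) / (a^2 + c14 a + c15)
    mu    = c21 exp(c22 a) + c23 exp(c24 a)
    sigma = c31 + c32 cos(c34 a) + c33 sin(c34 a)

The passive component combines a base-10 logistic sigmoid (rising between
plateaus f1 and f2 around the fibre-breaking length f4 with rate f3) and a
decaying exponential that makes the passive force negative below L = 1,
which is what places an activation-dependent rest length (zero-force
length) on the ascending limb:

    Fp = f1 + (f2 - f1) / (1 + 10**(f3*(f4 - L))) + f5 * exp(f6 * L)

Lengths are normalized to the optimal length Lo and forces to the maximal
active force Fo.  Evaluations outside alpha in [0, 120] pps or L in
[0.3, 1.8] Lo emit a warning (not an error) so that extraction pipelines
can probe the edges of the fitted domain.

The module also provides per-activation Gaussian slice fitting
(:func:`fit_gaussian_slice`, :func:`fit_active_slices`) used to recover
A, mu and sigma from noisy force-surface tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GaussianActiveParams",
    "PassiveParams",
    "EvaluationModel",
    "ModelDomainWarning",
    "fit_gaussian_slice",
    "fit_active_slices",
]

ALPHA_RANGE = (0.0, 120.0)
LENGTH_RANGE = (0.3, 1.8)


class ModelDomainWarning(UserWarning):
    """Evaluation requested outside the fitted (alpha, L) domain."""


def _warn_domain(alpha=None, L=None) -> None:
    if alpha is not None:
        a = np.asarray(alpha, dtype=float)
        if np.any(a < ALPHA_RANGE[0]) or np.any(a > ALPHA_RANGE[1]):
            warnings.warn(
                f"alpha outside the fitted range {ALPHA_RANGE} pps",
                ModelDomainWarning,
                stacklevel=3,
            )
    if L is not None:
        ell = np.asarray(L, dtype=float)
        if np.any(ell < LENGTH_RANGE[0]) or np.any(ell > LENGTH_RANGE[1]):
            warnings.warn(
                f"L outside the fitted range {LENGTH_RANGE} Lo",
                ModelDomainWarning,
                stacklevel=3,
            )


@dataclass(frozen=True)
class GaussianActiveParams:
    """Coefficients of the activation-dependent Gaussian active force.

    ``row1`` parameterizes the amplitude rational function (c11..c15),
    ``row2`` the double-exponential mean (c21..c24) and ``row3`` the
    trigonometric width (c31..c34).
    """

    row1: tuple = (1.134, 0.723, 0.0504, 11.3297, 643.259)
    row2: tuple = (0.574, -0.0211, 0.8477, 0.0008)
    row3: tuple = (0.4518, -0.01704, -0.1235, 0.04898)

    def __post_init__(self) -> None:
        if len(self.row1) != 5 or len(self.row2) != 4 or len(self.row3) != 4:
            raise ValueError("rows must have lengths 5, 4 and 4")
        # denominator a^2 + c14 a + c15 must not vanish on [0, 120]
        _, _, _, c14, c15 = self.row1
        a = np.linspace(*ALPHA_RANGE, 1201)
        if np.any(a * a + c14 * a + c15 <= 0):
            raise ValueError("amplitude denominator has a root in [0, 120] pps")
        c31, c32, c33, c34 = self.row3
        sigma = c31 + c32 * np.cos(c34 * a) + c33 * np.sin(c34 * a)
        if np.any(sigma <= 0):
            raise ValueError("width sigma(alpha) must be positive on [0, 120] pps")


@dataclass(frozen=True)
class PassiveParams:
    """Coefficients f1..f6 of the sigmoid-plus-exponential passive force."""

    f1: float = 0.00381
    f2: float = 2.16582
    f3: float = 8.16634
    f4: float = 1.45388
    f5: float = -7.32
    f6: float = -7.4

    def __post_init__(self) -> None:
        if self.f3 <= 0:
            raise ValueError("f3 must be positive (sigmoid rises with L)")
        if self.f6 >= 0:
            raise ValueError("f6 must be negative (decaying exponential)")


@dataclass(frozen=True)
class EvaluationModel:
    """Gaussian-active plus sigmoid/exponential-passive isometric force model."""

    active: GaussianActiveParams = field(default_factory=GaussianActiveParams)
    passive: PassiveParams = field(default_factory=PassiveParams)

    def amplitude(self, alpha):
        """Peak active force A(alpha), normalized to Fo."""
        _warn_domain(alpha=alpha)
        a = np.asarray(alpha, dtype=float)
        c11, c12, c13, c14, c15 = self.active.row1
        out = (c11 * a * a + c12 * a + c13) / (a * a + c14 * a + c15)
        return out if out.ndim else float(out)

    def mean_length(self, alpha):
        """Optimal (peak-force) length mu(alpha), normalized to Lo."""
        _warn_domain(alpha=alpha)
        a = np.asarray(alpha, dtype=float)
        c21, c22, c23, c24 = self.active.row2
        out = c21 * np.exp(c22 * a) + c23 * np.exp(c24 * a)
        return out if out.ndim else float(out)

    def width(self, alpha):
        """Gaussian width sigma(alpha), normalized to Lo; always positive."""
        _warn_domain(alpha=alpha)
        a = np.asarray(alpha, dtype=float)
        c31, c32, c33, c34 = self.active.row3
        out = c31 + c32 * np.cos(c34 * a) + c33 * np.sin(c34 * a)
        if np.any(np.asarray(out) <= 0):
            raise ValueError(f"nonpositive width at alpha={alpha}")
        return out if out.ndim else float(out)

    def active_force(self, alpha, L):
        """Gaussian active force FL(alpha, L)."""
        _warn_domain(alpha=alpha, L=L)
        ell = np.asarray(L, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ModelDomainWarning)
            A = self.amplitude(alpha)
            mu = self.mean_length(alpha)
            sigma = self.width(alpha)
        out = A * np.exp(-(((ell - mu) / sigma) ** 2))
        return out if np.ndim(out) else float(out)

    def passive_force(self, L):
        """Sigmoid-plus-exponential passive force Fp(L)."""
        _warn_domain(L=L)
        ell = np.asarray(L, dtype=float)
        p = self.passive
        sig = p.f1 + (p.f2 - p.f1) / (1.0 + 10.0 ** (p.f3 * (p.f4 - ell)))
        out = sig + p.f5 * np.exp(p.f6 * ell)
        return out if out.ndim else float(out)

    def unsaturated(self, alpha, L):
        """FL + Fp without the zero saturation (used for rest-length extraction)."""
        return self.active_force(alpha, L) + self.passive_force(L)

    def total_isometric(self, alpha, L):
        """Total isometric force max(0, FL + Fp)."""
        out = np.maximum(0.0, self.unsaturated(alpha, L))
        return out if np.ndim(out) else float(out)

    # convenience for force-surface export
    def surface(self, alphas, Ls) -> "np.ndarray":
        """Total isometric force on the outer grid alphas x Ls."""
        A, L = np.meshgrid(np.asarray(alphas, float), np.asarray(Ls, float), indexing="ij")
        return np.maximum(0.0, self.active_force(A, L) + self.passive_force(L))


def _gauss(L, A, mu, sigma):
    return A * np.exp(-(((L - mu) / sigma) ** 2))


def fit_gaussian_slice(L, F, p0=None):
    """Fit A * exp(-((L - mu)/sigma)^2) to one constant-activation slice.

    Returns (A, mu, sigma) with sigma > 0.  ``p0`` optionally seeds the
    nonlinear least squares; otherwise moment-based starting values are used.
    """
    L = np.asarray(L, dtype=float)
    F = np.asarray(F, dtype=float)
    if L.size < 4:
        raise ValueError("need at least 4 points to fit a Gaussian slice")
    if p0 is None:
        i = int(np.argmax(F))
        p0 = (max(float(F[i]), 1e-3), float(L[i]), 0.4)
    popt, _ = curve_fit(_gauss, L, F, p0=p0, maxfev=10000)
    A, mu, sigma = popt
    return float(A), float(mu), float(abs(sigma))


def fit_active_slices(surface):
    """Fit per-activation Gaussian slices of an active-force surface table.

    ``surface`` is a DataFrame with columns (alpha_pps, L_norm, F_norm).
    Returns a DataFrame with one row per distinct alpha and columns
    (alpha_pps, A, mu, sigma).
    """
    import pandas as pd

    rows = []
    for alpha, grp in surface.groupby("alpha_pps"):
        A, mu, sigma = fit_gaussian_slice(grp["L_norm"].to_numpy(), grp["F_norm"].to_numpy())
        rows.append({"alpha_pps": float(alpha), "A": A, "mu": mu, "sigma": sigma})
    return pd.DataFrame(rows)
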
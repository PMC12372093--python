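"""Reference isometric/contractile muscle models from the literature.

Two classic normalized Hill-type descriptions are provided for comparison
with the package's own models:

* the Brown-style contractile-element model, F_CE = Af * FL * FV + Fp,
  with an activation-frequency shape factor Nf(L), a force-length bell
  FL(L), a small negative passive term Fp(L) and a branched force-velocity
  scaling FV(L, Ldot);
* the Winters-style isometric model, F_ISO = FL + Fp, with a Gaussian
  active force whose mean shifts with activation and a piecewise
  exponential passive force that is negative below the optimal length.

All lengths are normalized to the optimal length Lo and forces to the
maximal active force Fo.  The Brown activation argument ``alpha`` is a
*normalized* activation (dimensionless); the package's own muscle models
take motoneuron firing rates in pulses per second (pps) instead, and
:func:`pps_to_normalized` converts between the two scales.  The two scales
are never mixed implicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BrownParams",
    "WintersParams",
    "MuscleState",
    "pps_to_normalized",
    "brown_nf",
    "brown_af",
    "brown_fl",
    "brown_fp",
    "brown_fv",
    "brown_fce",
    "winters_lce",
    "winters_fl",
    "winters_fp",
]

#: Maximal alpha-motoneuron firing rate (pps); activation is normalized by it.
ALPHA_MAX_PPS = 120.0


def pps_to_normalized(alpha_pps: float) -> float:
    """Convert an alpha-motoneuron firing rate in pps to normalized activation."""
    return alpha_pps / ALPHA_MAX_PPS


@dataclass(frozen=True)
class BrownParams:
    """Constants of the Brown-style contractile-element model."""

    af_scale: float = 0.56
    nf_offset: float = 2.11
    nf_slope: float = 4.16
    fl_exp1: float = 1.93
    fl_scale: float = 1.03
    fl_exp2: float = 1.87
    fp_amp: float = -0.02
    fp_a: float = 13.8
    fp_b: float = 18.7
    fv_vmax: float = -5.72
    fv_c0: float = 1.38
    fv_c1: float = 2.09
    fv_a0: float = 2.5
    fv_a1: float = 4.21
    fv_a2: float = 2.67
    fv_b: float = 0.62

    def __post_init__(self) -> None:
        if self.fv_vmax >= 0:
            raise ValueError("fv_vmax must be negative (maximal shortening velocity)")
        if self.fl_scale <= 0:
            raise ValueError("fl_scale must be positive")


@dataclass(frozen=True)
class WintersParams:
    """Constants of the Winters-style isometric model."""

    mean_base: float = 1.05
    mean_shift: float = 0.2
    width: float = 0.42
    fp_hi_rate: float = 30.6
    fp_hi_norm: float = math.exp(3.0) - 1.0
    fp_lo_rate: float = 60.7
    fp_lo_norm: float = math.exp(6.0) - 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.fp_hi_norm <= 0 or self.fp_lo_norm <= 0:
            raise ValueError("passive normalization constants must be positive")


@dataclass(frozen=True)
class MuscleState:
    """Instantaneous muscle state (activation, length, length rate)."""

    alpha: float
    L: float
    Ldot: float = 0.0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")


_DEFAULT_BROWN = BrownParams()
_DEFAULT_WINTERS = WintersParams()


def brown_nf(L: float, params: BrownParams = _DEFAULT_BROWN) -> float:
    """Activation-frequency shape factor Nf(L) = 2.11 + 4.16*(1/L - 1)."""
    if L <= 0:
        raise ValueError(f"L must be positive, got {L}")
    return params.nf_offset + params.nf_slope * (1.0 / L - 1.0)


def brown_af(alpha: float, L: float, params: BrownParams = _DEFAULT_BROWN) -> float:
    """Activation fraction Af = 1 - exp(-(alpha / (0.56 Nf))**Nf), in [0, 1).

    ``alpha`` is normalized activation (dimensionless, >= 0).
    """
    if alpha < 0:
        raise ValueError(f"alpha must be nonnegative, got {alpha}")
    nf = brown_nf(L, params)
    if alpha == 0.0:
        return 0.0
    return 1.0 - math.exp(-((alpha / (params.af_scale * nf)) ** nf))


def brown_fl(L: float, params: BrownParams = _DEFAULT_BROWN) -> float:
    # FL = exp(-|(L^1.93 - 1)/1.03|^1.87): bell with maximum 1 at L = 1.
    if L <= 0:
        raise ValueError(f"L must be positive, got {L}")
    z = (L**params.fl_exp1 - 1.0) / params.fl_scale
    return math.exp(-(abs(z) ** params.fl_exp2))


def brown_fp(L: float, params: BrownParams = _DEFAULT_BROWN) -> float:
    """Small negative passive term Fp = -0.02 exp(13.8 - 18.7 L)."""
    if L <= 0:
        raise ValueError(f"L must be positive, got {L}")
    return params.fp_amp * math.exp(params.fp_a - params.fp_b * L)


def brown_fv(L: float, Ldot: float, params: BrownParams = _DEFAULT_BROWN) -> float:
    """Force-velocity scaling, branched at Ldot = 0.

    Shortening branch (Ldot <= 0): (vmax - Ldot) / (vmax + (c0 + c1 L) Ldot).
    Lengthening branch (Ldot > 0): (a0 + a1 L + a2 L^2) * Ldot / (b + Ldot).
    The branches do not meet at Ldot -> 0+; the discontinuity is intrinsic
    to the published form and is preserved here.
    """
    if Ldot <= 0:
        den = params.fv_vmax + (params.fv_c0 + params.fv_c1 * L) * Ldot
        if den == 0.0:
            raise ZeroDivisionError(f"singular shortening denominator at Ldot={Ldot}")
        return (params.fv_vmax - Ldot) / den
    den = params.fv_b + Ldot
    if den == 0.0:
        raise ZeroDivisionError(f"singular lengthening denominator at Ldot={Ldot}")
    return (params.fv_a0 + params.fv_a1 * L + params.fv_a2 * L * L) * Ldot / den


def brown_fce(
    alpha: float, L: float, Ldot: float, params: BrownParams = _DEFAULT_BROWN
) -> float:
    """Contractile-element force F_CE = Af(alpha, L) * FL(L) * FV(L, Ldot) + Fp(L)."""
    return (
        brown_af(alpha, L, params) * brown_fl(L, params) * brown_fv(L, Ldot, params)
        + brown_fp(L, params)
    )


def winters_lce(Lmt: float, Lt0: float, xSE: float, Lm0: float) -> float:
    """Contractile-element length L_CE = Lmt - Lt0 - xSE*(Lm0 + Lt0)."""
    if Lm0 <= 0:
        raise ValueError(f"Lm0 must be positive, got {Lm0}")
    return Lmt - Lt0 - xSE * (Lm0 + Lt0)


def winters_fl(
    alpha: float, Lhat: float, params: WintersParams = _DEFAULT_WINTERS
) -> float:
    """Gaussian active force with activation-shifted mean.

    FL = alpha * exp(-[(Lhat - (1.05 + 0.2*(1 - alpha))) / 0.42]^2), where
    ``Lhat`` is the contractile-element length normalized by the optimal
    length and ``alpha`` is normalized activation in [0, 1].  As activation
    drops, the peak moves to longer lengths.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    mean = params.mean_base + params.mean_shift * (1.0 - alpha)
    return alpha * math.exp(-(((Lhat - mean) / params.width) ** 2))


def winters_fp(Lhat: float, params: WintersParams = _DEFAULT_WINTERS) -> float:
    """Piecewise passive force, negative below the optimal length.

    [exp(30.6*(Lhat-1)) - 1]/(e^3 - 1) for Lhat >= 1, and
    -[exp(60.7*(1-Lhat)) - 1]/(e^6 - 1) for Lhat < 1; continuous at Lhat = 1.
    """
    if Lhat <= 0:
        raise ValueError(f"Lhat must be positive, got {Lhat}")
    if Lhat >= 1.0:
        return (math.exp(params.fp_hi_rate * (Lhat - 1.0)) - 1.0) / params.fp_hi_norm
    return -(math.exp(params.fp_lo_rate * (1.0 - Lhat)) - 1.0) / params.fp_lo_norm
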
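"""Controllable nonlinear-spring muscle model ("Control Model") and its
generation pipeline.

The isometric force is written as a spring law with activation-dependent
rest length and a bivariate polynomial stiffness,

    F_ISO(alpha, L) = K(alpha, L) * (L - L0(alpha)),

with

    L0(alpha) = l1 alpha^2 + l2 alpha + l3
    K(alpha, L) = k1(L) alpha^3 + k2(L) alpha^2 + k3(L) alpha + k4(L)
    ki(L) = ki1 L^6 + ki2 L^5 + ... + ki7

(alpha in pps, L in Lo units, K dimensionless, forces in Fo units).  The
rest length L0 is the zero-force length at a given firing rate, so
F_ISO(alpha, L0(alpha)) = 0 holds structurally.

The shipped default coefficient tables are illustrative: the stiffness
table's rows multiplying alpha^3..alpha are near-cancelling sums whose
printed rounding is amplified by alpha^3 up to 120^3 ~ 1.7e6, so values
computed from the printed coefficients are numerically reliable only at
small alpha (tests pin them at alpha = 0, where only k4 contributes).
The supported quantitative path is regeneration of both polynomial
families from an :class:`~myospring.evaluation.EvaluationModel` via
:func:`extract_rest_points`, :func:`extract_stiffness_points`,
:func:`fit_rest_length` and :func:`fit_stiffness` — bundled in
:func:`fit_control_model`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .evaluation import EvaluationModel, ModelDomainWarning

__all__ = [
    "RestLengthParams",
    "StiffnessParams",
    "ControlModel",
    "ExtractedPoints",
    "FitReport",
    "ExtractionError",
    "extract_rest_points",
    "extract_stiffness_points",
    "fit_rest_length",
    "fit_stiffness",
    "fit_control_model",
    "residual_norm",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_LENGTH_GRID",
]

#: Validity box of the spring model: L in [0.4, 1.5] Lo, alpha in [0, 120] pps.
VALID_ALPHA = (0.0, 120.0)
VALID_LENGTH = (0.4, 1.5)

#: Default extraction grids spanning the validity box.
DEFAULT_ALPHA_GRID = tuple(float(a) for a in range(0, 121, 10))
DEFAULT_LENGTH_GRID = tuple(np.round(np.arange(0.40, 1.5001, 0.05), 10))

#: Refined grids used for the stiffness surface fit.  The passive force
#: rises steeply near the fibre-breaking length (~1.45 Lo); at the coarse
#: grid spacing the fitted polynomial is uncontrolled between nodes there,
#: so the stiffness fit samples twice as densely in both variables.
DEFAULT_FIT_ALPHA_GRID = tuple(float(a) for a in range(0, 121, 5))
DEFAULT_FIT_LENGTH_GRID = tuple(np.round(np.arange(0.40, 1.5001, 0.025), 10))

#: Pointwise bound (Fo units) imposed on the force residual during the
#: stiffness fit, so the spring model approximates the Evaluation Model
#: uniformly instead of letting least squares concentrate error at the
#: passive-force wall.
DEFAULT_FORCE_CAP = 0.075

#: Exclusion radius around the rest length when forming stiffness quotients
#: (bounds the quotient's noise amplification near the structural zero).
REST_EXCLUSION_RADIUS = 0.02

ALPHA_SCALE = 120.0  # internal scaling of alpha for conditioning of the LSQ fit


class ExtractionError(RuntimeError):
    """Rest-length or stiffness extraction failed."""


@dataclass(frozen=True)
class RestLengthParams:
    """Quadratic rest-length law L0(alpha) = l1 a^2 + l2 a + l3."""

    l1: float = 6.794e-5
    l2: float = -0.01271
    l3: float = 1.0

    def __post_init__(self) -> None:
        a = np.linspace(*VALID_ALPHA, 121)
        L0 = self.l1 * a * a + self.l2 * a + self.l3
        if np.any(L0 <= 0) or np.any(L0 > 1.2):
            raise ValueError("rest length must lie in (0, 1.2] Lo on [0, 120] pps")


_DEFAULT_K = (
    (-0.00041, 0.0025, -0.0061, 0.00763, -0.0052, 0.0018, -0.00026),
    (0.0586, -0.352, 0.8444, -1.0277, 0.6697, -0.2257, 0.0319),
    (-1.67504, 9.829, -22.692, 25.896, -15.268, 4.5087, -0.5351),
    (-40.977, 244.666, -569.9335, 664.1912, -405.645, 120.853, -13.045),
)


@dataclass(frozen=True)
class StiffnessParams:
    """4x7 stiffness coefficient matrix.

    Row i (i = 1..4) holds the L-polynomial multiplying alpha^(4-i); within
    a row, columns run from the L^6 coefficient down to the constant.
    """

    k: tuple = _DEFAULT_K

    def __post_init__(self) -> None:
        arr = np.asarray(self.k, dtype=float)
        if arr.shape != (4, 7):
            raise ValueError(f"stiffness matrix must be 4x7, got {arr.shape}")
        object.__setattr__(self, "k", tuple(tuple(row) for row in arr))

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.k, dtype=float)


def _warn_box(alpha, L) -> None:
    a = np.asarray(alpha, float)
    ell = np.asarray(L, float)
    if np.any(a < VALID_ALPHA[0]) or np.any(a > VALID_ALPHA[1]):
        warnings.warn(
            f"alpha outside the validity box {VALID_ALPHA} pps",
            ModelDomainWarning,
            stacklevel=3,
        )
    if np.any(ell < VALID_LENGTH[0]) or np.any(ell > VALID_LENGTH[1]):
        warnings.warn(
            f"L outside the validity box {VALID_LENGTH} Lo",
            ModelDomainWarning,
            stacklevel=3,
        )


@dataclass(frozen=True)
class ControlModel:
    """Controllable nonlinear spring F_ISO = K(alpha, L) * (L - L0(alpha))."""

    rest: RestLengthParams = field(default_factory=RestLengthParams)
    stiff: StiffnessParams = field(default_factory=StiffnessParams)
    saturate_negative: bool = True

    def rest_length(self, alpha):
        """Zero-force length L0(alpha), Lo units."""
        _warn_box(alpha, VALID_LENGTH[0])
        a = np.asarray(alpha, dtype=float)
        r = self.rest
        out = r.l1 * a * a + r.l2 * a + r.l3
        return out if out.ndim else float(out)

    def stiffness(self, alpha, L):
        """Bivariate polynomial stiffness K(alpha, L), Horner form in both variables."""
        _warn_box(alpha, L)
        a = np.asarray(alpha, dtype=float)
        ell = np.asarray(L, dtype=float)
        kmat = self.stiff.matrix
        # Horner in L for each row, then Horner in alpha over the row values.
        rows = [np.polynomial.polynomial.polyval(ell, row[::-1]) for row in kmat]
        out = rows[0]
        for r in rows[1:]:
            out = out * a + r
        return out if np.ndim(out) else float(out)

    def iso_force(self, alpha, L):
        """Spring force K * (L - L0); clamped below at 0 if ``saturate_negative``."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ModelDomainWarning)
            K = self.stiffness(alpha, L)
            L0 = self.rest_length(alpha)
        _warn_box(alpha, L)
        out = K * (np.asarray(L, float) - L0)
        if self.saturate_negative:
            out = np.maximum(0.0, out)
        return out if np.ndim(out) else float(out)

    def unsaturated(self, alpha, L):
        """Spring force without the zero clamp (regardless of the flag)."""
        if self.saturate_negative:
            return replace(self, saturate_negative=False).iso_force(alpha, L)
        return self.iso_force(alpha, L)


@dataclass(frozen=True)
class ExtractedPoints:
    """Rest-length and stiffness samples extracted from an Evaluation Model."""

    rest_points: tuple  # ((alpha_pps, L0), ...)
    stiffness_points: tuple  # ((alpha_pps, L, K), ...)


@dataclass(frozen=True)
class FitReport:
    """Least-squares diagnostics of the model-generation pipeline."""

    rest_residual_norm: float
    stiffness_residual_norm: float
    stiffness_condition_number: float
    n_rest_points: int
    n_stiffness_points: int
    force_max_abs_error: float | None = None
    force_rms_error: float | None = None


def extract_rest_points(
    em: EvaluationModel,
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
    *,
    tol: float = 1e-10,
    search_floor: float = 0.25,
) -> tuple:
    """Ascending-limb zero crossings of the unsaturated force, per activation.

    For each firing rate the largest L below the optimal length mu(alpha)
    where FL + Fp changes sign is located by bracketing on a fine grid and
    refined by bisection (``brentq``).  The descending-limb zero beyond the
    Gaussian tail is deliberately ignored: the ascending-limb root is the
    physiologically meaningful rest length.
    """
    points = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ModelDomainWarning)
        for alpha in alphas:
            upper = float(em.mean_length(alpha))
            grid = np.linspace(upper, search_floor, 400)
            vals = em.unsaturated(alpha, grid)
            idx = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
            if idx.size == 0:
                raise ExtractionError(
                    f"no rest-length sign change below mu for alpha={alpha} pps"
                )
            i = idx[0]  # first crossing walking down from the optimum
            lo, hi = grid[i + 1], grid[i]
            root = brentq(lambda L: em.unsaturated(alpha, L), lo, hi, xtol=tol)
            points.append((float(alpha), float(root)))
    return tuple(points)


def extract_stiffness_points(
    em: EvaluationModel,
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
    Ls: Sequence[float] = DEFAULT_LENGTH_GRID,
    rest: RestLengthParams | None = None,
    *,
    delta: float = REST_EXCLUSION_RADIUS,
) -> tuple:
    """Equivalent stiffness samples K = (FL + Fp) / (L - L0(alpha)).

    Grid nodes closer than ``delta`` to the rest length are excluded: there
    the quotient amplifies any imperfection of the rest-length law.
    """
    if rest is None:
        rest = RestLengthParams()
    tmp = ControlModel(rest=rest)
    points = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ModelDomainWarning)
        for alpha in alphas:
            L0 = float(tmp.rest_length(alpha))
            for L in Ls:
                elong = float(L) - L0
                if abs(elong) < delta:
                    continue
                F = float(em.unsaturated(alpha, L))
                points.append((float(alpha), float(L), F / elong))
    if not points:
        raise ExtractionError("all grid nodes fell inside the rest-length exclusion")
    return tuple(points)


def fit_rest_length(points: Sequence) -> tuple[RestLengthParams, float]:
    """Least-squares quadratic fit of rest-length points (alpha, L0).

    Returns the fitted parameters and the residual norm.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (alpha, L0) points for a quadratic fit")
    a, L0 = pts[:, 0], pts[:, 1]
    X = np.column_stack([a * a, a, np.ones_like(a)])
    coef, _, rank, _ = np.linalg.lstsq(X, L0, rcond=None)
    if rank < 3:
        raise np.linalg.LinAlgError("rank-deficient rest-length design matrix")
    res = float(np.linalg.norm(X @ coef - L0))
    return RestLengthParams(*[float(c) for c in coef]), res


def _stiffness_design(alpha, L) -> np.ndarray:
    """28-column design matrix (alpha^3..alpha^0) x (L^6..L^0), alpha scaled."""
    a = np.asarray(alpha, float) / ALPHA_SCALE
    ell = np.asarray(L, float)
    return np.column_stack([a**p * ell**q for p in (3, 2, 1, 0) for q in range(6, -1, -1)])


def _unscale_coef(coef: np.ndarray) -> StiffnessParams:
    kmat = coef.reshape(4, 7).copy()
    # row for alpha^p was fitted against (alpha/120)^p
    for i, p in enumerate((3, 2, 1, 0)):
        kmat[i] /= ALPHA_SCALE**p
    return StiffnessParams(tuple(map(tuple, kmat)))


def fit_stiffness(
    points: Sequence,
    *,
    rest: RestLengthParams | None = None,
    force_cap: float | None = None,
) -> tuple[StiffnessParams, float, float]:
    """Fit the 28-term stiffness basis {alpha^3..1} x {L^6..1} to K samples.

    Alpha is scaled internally to alpha/120 to control the conditioning of
    the design matrix; the returned coefficients are on the raw-alpha scale.
    Returns (params, residual_norm, condition_number); the residual norm is
    over the stiffness values K.

    Plain (unweighted) linear least squares on K is used unless both
    ``rest`` and ``force_cap`` are given.  In that case the fit instead
    minimizes the squared *force* residual (elongation-weighted stiffness
    residual) subject to a pointwise bound of ``force_cap`` on the
    zero-saturated force residual at every sample — a small quadratic
    program solved after QR preconditioning.  The capped form is what the
    model-generation pipeline uses: unconstrained least squares lets the
    steep passive-force wall near 1.45 Lo accumulate localized force
    errors well above the fit's RMS.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 28:
        raise ValueError("need at least 28 (alpha, L, K) points for the 4x7 basis")
    alpha, L, K = pts[:, 0], pts[:, 1], pts[:, 2]
    X = _stiffness_design(alpha, L)
    cond = float(np.linalg.cond(X))

    if rest is None or force_cap is None:
        coef, _, rank, _ = np.linalg.lstsq(X, K, rcond=None)
        if rank < 28:
            raise np.linalg.LinAlgError(
                f"rank-deficient stiffness design matrix (rank {rank} < 28)"
            )
        res = float(np.linalg.norm(X @ coef - K))
        return _unscale_coef(coef), res, cond

    from scipy.optimize import LinearConstraint, minimize

    elong = L - (rest.l1 * alpha**2 + rest.l2 * alpha + rest.l3)
    Xe = X * elong[:, None]
    f_target = np.maximum(0.0, K * elong)  # saturated Evaluation-Model force
    Q, R = np.linalg.qr(Xe)
    if min(Q.shape) < 28 or np.abs(np.diag(R)).min() <= 0:
        raise np.linalg.LinAlgError("rank-deficient stiffness design matrix")
    pos = f_target > 0
    # where the target force is positive: two-sided cap on the residual;
    # where it is zero (below rest length): the spring must not push harder
    # than the cap, but any nonpositive prediction saturates to zero error.
    A_con = np.vstack([Q[pos], Q[~pos]])
    lb = np.concatenate([f_target[pos] - force_cap, np.full((~pos).sum(), -np.inf)])
    ub = np.concatenate([f_target[pos] + force_cap, np.full((~pos).sum(), force_cap)])
    b = Q.T @ f_target
    sol = minimize(
        lambda y: 0.5 * y @ y - b @ y,
        b,
        jac=lambda y: y - b,
        method="SLSQP",
        constraints=[LinearConstraint(A_con, lb, ub)],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not sol.success:
        raise RuntimeError(f"capped stiffness fit did not converge: {sol.message}")
    coef = np.linalg.solve(R, sol.x)
    res = float(np.linalg.norm(X @ coef - K))
    return _unscale_coef(coef), res, cond


def residual_norm(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Euclidean norm of the residual vector predicted - observed."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    return float(np.linalg.norm(p - o))


def fit_control_model(
    em: EvaluationModel | None = None,
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
    Ls: Sequence[float] = DEFAULT_FIT_LENGTH_GRID,
    *,
    fit_alphas: Sequence[float] = DEFAULT_FIT_ALPHA_GRID,
    delta: float = REST_EXCLUSION_RADIUS,
    force_cap: float | None = DEFAULT_FORCE_CAP,
    saturate_negative: bool = True,
) -> tuple[ControlModel, ExtractedPoints, FitReport]:
    """Full model-generation pipeline: extract, refit, and report.

    Rest-length points come from ascending-limb zero crossings of the
    Evaluation Model on the ``alphas`` grid and are refit by a quadratic;
    stiffness points come from the force/elongation quotient on the denser
    (``fit_alphas`` x ``Ls``) grid and are refit on the 28-term basis with
    the pointwise force-residual cap (see :func:`fit_stiffness`).  The
    report includes the force error of the refit spring against the
    Evaluation Model over the validity box.
    """
    if em is None:
        em = EvaluationModel()
    rest_pts = extract_rest_points(em, alphas)
    rest, rest_res = fit_rest_length(rest_pts)
    stiff_pts = extract_stiffness_points(em, fit_alphas, Ls, rest, delta=delta)
    stiff, stiff_res, cond = fit_stiffness(stiff_pts, rest=rest, force_cap=force_cap)
    model = ControlModel(rest=rest, stiff=stiff, saturate_negative=saturate_negative)

    # compare saturated forces over the validity box on a finer grid
    a_grid = np.linspace(*VALID_ALPHA, 25)
    L_grid = np.linspace(*VALID_LENGTH, 111)
    A, L = np.meshgrid(a_grid, L_grid, indexing="ij")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ModelDomainWarning)
        f_em = np.maximum(0.0, em.unsaturated(A, L))
        f_cm = np.maximum(0.0, model.unsaturated(A, L))
    err = f_cm - f_em
    report = FitReport(
        rest_residual_norm=rest_res,
        stiffness_residual_norm=stiff_res,
        stiffness_condition_number=cond,
        n_rest_points=len(rest_pts),
        n_stiffness_points=len(stiff_pts),
        force_max_abs_error=float(np.max(np.abs(err))),
        force_rms_error=float(np.sqrt(np.mean(err**2))),
    )
    points = ExtractedPoints(rest_points=rest_pts, stiffness_points=stiff_pts)
    return model, points, report
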
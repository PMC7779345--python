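"""Linear-quadratic (LQ) survival model on a dose or OH-radical-count axis.

The clonogenic surviving fraction after an exposure ``x`` is modelled as

    SF(x) = exp(-(alpha * x + beta * x**2))

where ``x`` is the absorbed dose D in Gy (``axis="dose"``) or the number of
OH radicals produced per liter of water (``axis="radicals"``).  The same
functional form is fitted on either axis; only the units of alpha and beta
change.  Because ``-ln SF`` is linear in (alpha, beta), fitting is a
non-negative linear least-squares problem and needs no iterative optimizer.

D10-type quantities (the exposure at which SF reaches a given level, 0.1 by
convention) come from the closed-form inversion, and RBE at a survival level
is the ratio of two such inversions on the dose axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from .errors import (
    AxisMismatchError,
    DomainError,
    FitError,
    InsufficientDataError,
    NoSolutionError,
    ValidationError,
)

AXES = ("dose", "radicals")

#: Internal exposure unit for the radical axis.  Raw radical counts are
#: ~1e17-1e18 per liter; fitting in units of 1e17/L keeps the normal
#: equations well conditioned.  Reported parameters are converted back.
RADICAL_SCALE = 1e17


def _check_axis(axis: str) -> str:
    if axis not in AXES:
        raise ValidationError(f"axis must be one of {AXES}, got {axis!r}")
    return axis


@dataclass(frozen=True)
class SurvivalPoint:
    """One (exposure, surviving fraction) observation.

    ``sf_err``, when present, is one standard deviation of ``sf``.
    """

    exposure: float
    sf: float
    sf_err: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.exposure) or self.exposure < 0:
            raise ValidationError(f"exposure must be finite and >= 0, got {self.exposure}")
        if not np.isfinite(self.sf) or not (0.0 < self.sf <= 1.0):
            raise ValidationError(f"sf must be in (0, 1], got {self.sf}")
        if self.sf_err is not None and not (np.isfinite(self.sf_err) and self.sf_err > 0):
            raise ValidationError(f"sf_err must be > 0 when present, got {self.sf_err}")


@dataclass(frozen=True)
class SurvivalCurveData:
    """One radiation quality's survival curve: points plus LET and axis tag."""

    label: str
    let_value: float
    axis: str
    points: tuple[SurvivalPoint, ...]

    def __post_init__(self) -> None:
        _check_axis(self.axis)
        if not (np.isfinite(self.let_value) and self.let_value > 0):
            raise ValidationError(f"let_value must be > 0, got {self.let_value}")
        pts = tuple(self.points)
        object.__setattr__(self, "points", pts)
        exposures = [p.exposure for p in pts]
        if sorted(exposures) != exposures:
            raise ValidationError(f"curve {self.label!r}: points must be sorted by exposure")
        if len(set(exposures)) != len(exposures):
            raise ValidationError(f"curve {self.label!r}: duplicate exposures are not allowed")

    @property
    def exposures(self) -> np.ndarray:
        return np.array([p.exposure for p in self.points], dtype=float)

    @property
    def sf(self) -> np.ndarray:
        return np.array([p.sf for p in self.points], dtype=float)

    @property
    def sf_err(self) -> Optional[np.ndarray]:
        """Per-point uncertainties, or None if any point lacks one."""
        errs = [p.sf_err for p in self.points]
        if any(e is None for e in errs):
            return None
        return np.array(errs, dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class LQParameters:
    """Fitted (or true) LQ coefficients with their axis tag.

    alpha has units 1/Gy on the dose axis and liters per radical on the
    radical axis; beta the corresponding squared units.  ``covariance`` is
    the 2x2 covariance matrix of (alpha, beta) from the fit, when available.
    alpha = beta = 0 (a flat curve) is representable but cannot be inverted.
    """

    alpha: float
    beta: float
    axis: str
    covariance: Optional[np.ndarray] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        _check_axis(self.axis)
        if not (np.isfinite(self.alpha) and self.alpha >= 0):
            raise ValidationError(f"alpha must be finite and >= 0, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta >= 0):
            raise ValidationError(f"beta must be finite and >= 0, got {self.beta}")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            if cov.shape != (2, 2):
                raise ValidationError("covariance must be a 2x2 matrix")
            object.__setattr__(self, "covariance", cov)


def evaluate_sf(params: LQParameters, x) -> float | np.ndarray:
    """Surviving fraction SF(x) = exp(-(alpha x + beta x^2)).

    ``x`` may be a scalar or array; negative exposures raise DomainError.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or not np.all(np.isfinite(xa)):
        raise DomainError(f"exposure must be finite and >= 0, got {x}")
    out = np.exp(-(params.alpha * xa + params.beta * xa**2))
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


def invert_lq(params: LQParameters, sf_target: float) -> float:
    """Exposure at which the LQ curve reaches ``sf_target``.

    Uses the cancellation-free root x = 2L / (alpha + sqrt(alpha^2 + 4 beta L))
    with L = ln(1/sf_target); equivalent to the quadratic formula but stable
    for arbitrarily small beta, and reducing to L/alpha at beta = 0.
    """
    if not (0.0 < sf_target < 1.0):
        raise DomainError(f"sf_target must be in (0, 1), got {sf_target}")
    a, b = params.alpha, params.beta
    if a == 0.0 and b == 0.0:
        raise NoSolutionError("alpha = beta = 0: flat curve has no finite inverse")
    L = -math.log(sf_target)
    return 2.0 * L / (a + math.sqrt(a * a + 4.0 * b * L))


def rbe_at_level(reference: LQParameters, test: LQParameters, sf_target: float = 0.1) -> float:
    """Relative biological effectiveness at a survival level.

    Ratio of the reference radiation's iso-effect dose to the test
    radiation's (e.g. D10_xray / D10_ion at 10% survival).  Both parameter
    sets must be on the dose axis.
    """
    if reference.axis != "dose" or test.axis != "dose":
        raise AxisMismatchError(
            f"RBE is defined on the dose axis, got {reference.axis!r} and {test.axis!r}"
        )
    return invert_lq(reference, sf_target) / invert_lq(test, sf_target)


def fit_lq(curve: SurvivalCurveData, weighting: str = "none") -> LQParameters:
    """Fit the LQ model to a survival curve by non-negative least squares.

    The fit linearizes the model: y = -ln(sf) is regressed on [x, x^2] with
    alpha, beta >= 0.  ``weighting="inverse_variance"`` weights each point by
    1/var(ln sf) with var(ln sf) = (sf_err/sf)^2 (delta method); it requires
    every point to carry ``sf_err``.  The covariance of (alpha, beta) is
    (A' W A)^-1 for known weights, or the residual-scaled unweighted form.

    Radical-axis exposures are rescaled to units of ``RADICAL_SCALE`` per
    liter internally; the returned parameters are in the curve's own units.
    """
    if weighting not in ("none", "inverse_variance"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    if len(curve) < 3:
        raise InsufficientDataError(
            f"curve {curve.label!r}: need >= 3 points to fit, got {len(curve)}"
        )

    scale = RADICAL_SCALE if curve.axis == "radicals" else 1.0
    u = curve.exposures / scale
    y = -np.log(curve.sf)

    if weighting == "inverse_variance":
        errs = curve.sf_err
        if errs is None:
            raise ValidationError(
                f"curve {curve.label!r}: inverse_variance weighting needs sf_err on every point"
            )
        sigma_y = errs / curve.sf          # sd of ln(sf), delta method
        w = 1.0 / sigma_y
    else:
        w = np.ones_like(y)

    A = np.column_stack([u, u * u])
    Aw = A * w[:, None]
    yw = y * w
    try:
        coef, _ = nnls(Aw, yw)
    except Exception as exc:  # pragma: no cover - nnls failure is pathological
        raise FitError(f"curve {curve.label!r}: NNLS failed: {exc}") from exc
    if not np.all(np.isfinite(coef)):
        raise FitError(f"curve {curve.label!r}: non-finite fit result {coef}")

    # Covariance in internal units, then convert to the curve's units.
    M = Aw.T @ Aw
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        Minv = np.linalg.pinv(M)
    if weighting == "inverse_variance":
        cov_u = Minv
    else:
        resid = yw - Aw @ coef
        dof = max(len(y) - 2, 1)
        cov_u = Minv * float(resid @ resid) / dof

    J = np.diag([1.0 / scale, 1.0 / scale**2])
    cov = J @ cov_u @ J
    return LQParameters(
        alpha=float(coef[0] / scale),
        beta=float(coef[1] / scale**2),
        axis=curve.axis,
        covariance=cov,
    )


def make_curve(
    label: str,
    let_value: float,
    axis: str,
    exposures: Iterable[float],
    sf: Iterable[float],
    sf_err: Optional[Sequence[float]] = None,
) -> SurvivalCurveData:
    """Convenience constructor from parallel sequences (sorted by exposure)."""
    exposures = list(exposures)
    sf = list(sf)
    errs = list(sf_err) if sf_err is not None else [None] * len(exposures)
    if not (len(exposures) == len(sf) == len(errs)):
        raise ValidationError("exposures, sf and sf_err must have equal length")
    order = np.argsort(exposures, kind="stable")
    pts = tuple(SurvivalPoint(exposures[i], sf[i], errs[i]) for i in order)
    return SurvivalCurveData(label=label, let_value=let_value, axis=axis, points=pts)
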
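"""Synthetic clonogenic-assay data and G-value tables with known truth.

The generator emulates the phenomenology of published V79 carbon-ion
survival data and simulated OH-radical yields:

* alpha(LET) rises to a maximum near 140 keV/um and then declines
  (overkill), modelled as a log-normal-shaped bump over a floor;
* beta(LET) decays exponentially, so the survival shoulder shrinks and
  disappears at high LET;
* G(LET, t) declines with LET as a shifted exponential, with plateaus per
  time point; the decline is much stronger at 100 ns than at 1 ps, and the
  X-ray reference sits at LET 9.4 keV/um;
* observed colony counts are Binomial(cells_plated, PE * SF) per replicate
  dish — the canonical clonogenic-assay noise model.

Every generated artifact carries its ground-truth parameters, and
``ground_truth_dabble`` evaluates the whole decomposition in closed form
from those parameters, so the noisy fit->transform->DABBLE pipeline has an
exact recovery target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .decompose import DabbleResult, DecompositionConfig, dabble
from .errors import ValidationError
from .lq import LQParameters, SurvivalCurveData, SurvivalPoint, rbe_at_level
from .radicals import GValueTable, PhysicalConstants, make_gvalue_table

#: Default ion LET grid, keV/um — spans the range where published V79
#: carbon-ion curves sit (≈22.5 to 432 keV/um), 10 qualities.
DEFAULT_LET_GRID = (22.5, 35.0, 50.0, 70.0, 90.0, 110.0, 140.0, 200.0, 300.0, 432.0)

DEFAULT_DOSES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 8.0)

XRAY_LABEL = "200kVp-Xray"
XRAY_LET = 9.4  # keV/um, effective LET of 200 kVp X-rays


@dataclass(frozen=True)
class AlphaModel:
    """Unimodal alpha(LET): floor + amplitude * exp(-(ln(LET/peak))^2 / 2w^2).

    floor (1/Gy) is the low/high-LET baseline, amplitude the peak excess,
    peak_let the LET of maximal radiosensitivity, width the log-LET spread.
    """

    floor: float = 0.10
    amplitude: float = 1.2
    peak_let: float = 140.0
    width: float = 0.8

    def __post_init__(self) -> None:
        if self.floor < 0 or self.amplitude < 0 or self.peak_let <= 0 or self.width <= 0:
            raise ValidationError(f"invalid alpha model {self}")

    def __call__(self, let_value) -> np.ndarray | float:
        L = np.asarray(let_value, dtype=float)
        z = np.log(L / self.peak_let) / self.width
        out = self.floor + self.amplitude * np.exp(-0.5 * z * z)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BetaModel:
    """Decaying beta(LET) = beta0 * exp(-LET/let_scale): the shoulder fades."""

    beta0: float = 0.025
    let_scale: float = 80.0

    def __post_init__(self) -> None:
        if self.beta0 < 0 or self.let_scale <= 0:
            raise ValidationError(f"invalid beta model {self}")

    def __call__(self, let_value) -> np.ndarray | float:
        L = np.asarray(let_value, dtype=float)
        out = self.beta0 * np.exp(-L / self.let_scale)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SurvivalSimSpec:
    """Design of a synthetic clonogenic experiment across an LET grid."""

    let_grid: tuple[float, ...] = DEFAULT_LET_GRID
    alpha_model: AlphaModel = field(default_factory=AlphaModel)
    beta_model: BetaModel = field(default_factory=BetaModel)
    doses: tuple[float, ...] = DEFAULT_DOSES
    cells_plated: int = 500
    plating_efficiency: float = 0.8
    n_replicates: int = 3
    seed: int = 0
    xray_let: float = XRAY_LET

    def __post_init__(self) -> None:
        if len(self.let_grid) == 0 or any(l <= 0 for l in self.let_grid):
            raise ValidationError("let_grid must be non-empty and positive")
        if len(self.doses) == 0 or any(d <= 0 for d in self.doses):
            raise ValidationError("doses must be non-empty and positive")
        if self.cells_plated < 1 or self.n_replicates < 1:
            raise ValidationError("cells_plated and n_replicates must be >= 1")
        if not (0.0 < self.plating_efficiency <= 1.0):
            raise ValidationError("plating_efficiency must be in (0, 1]")
        if self.xray_let <= 0:
            raise ValidationError("xray_let must be > 0")

    def true_params(self, let_value: float) -> LQParameters:
        return LQParameters(
            alpha=float(self.alpha_model(let_value)),
            beta=float(self.beta_model(let_value)),
            axis="dose",
        )


@dataclass(frozen=True)
class GValueSimSpec:
    """Parametric G(LET, t) stand-in: G = ginf + (g0 - ginf) * exp(-LET/scale).

    Plateaus are per time point (species per 100 eV); the relative decline
    g0/ginf must be strictly stronger at 100 ns than at 1 ps, reflecting
    the more prominent intra-track radical-radical recombination seen late
    in the chemical phase.
    """

    g0_1ps: float = 5.5
    ginf_1ps: float = 4.2
    g0_100ns: float = 3.0
    ginf_100ns: float = 0.1
    let_scale: float = 100.0
    xray_let: float = XRAY_LET

    def __post_init__(self) -> None:
        for g0, ginf, tp in (
            (self.g0_1ps, self.ginf_1ps, "1ps"),
            (self.g0_100ns, self.ginf_100ns, "100ns"),
        ):
            if not (g0 >= ginf > 0):
                raise ValidationError(f"need g0 >= ginf > 0 at {tp}, got {g0}, {ginf}")
        if self.let_scale <= 0 or self.xray_let <= 0:
            raise ValidationError("let_scale and xray_let must be > 0")
        if not (self.g0_100ns / self.ginf_100ns > self.g0_1ps / self.ginf_1ps):
            raise ValidationError(
                "the 100 ns decline factor g0/ginf must exceed the 1 ps one"
            )

    def g(self, let_value, time_point: str) -> np.ndarray | float:
        """Closed-form G at any LET and time point."""
        if time_point == "1ps":
            g0, ginf = self.g0_1ps, self.ginf_1ps
        elif time_point == "100ns":
            g0, ginf = self.g0_100ns, self.ginf_100ns
        else:
            raise ValidationError(f"unknown time point {time_point!r}")
        L = np.asarray(let_value, dtype=float)
        out = ginf + (g0 - ginf) * np.exp(-L / self.let_scale)
        return float(out) if out.ndim == 0 else out


def generate_gvalue_table(
    spec: GValueSimSpec, let_grid: Optional[Sequence[float]] = None
) -> GValueTable:
    """Tabulate the G model on a LET grid plus the X-ray LET.

    Default grid: 25 log-spaced LETs from 5 to 600 keV/um, covering the
    ion range with margin for interpolation.
    """
    if let_grid is None:
        let_grid = np.geomspace(5.0, 600.0, 25)
    lets = np.unique(np.concatenate([np.asarray(let_grid, float), [spec.xray_let]]))
    rows = [
        (float(L), tp, float(spec.g(L, tp)))
        for tp in ("1ps", "100ns")
        for L in lets
    ]
    return make_gvalue_table(rows, provenance="synthetic: shifted-exponential G(LET) model")


@dataclass(frozen=True)
class SimulatedSurvival:
    """Generated curves plus the ground truth that produced them."""

    curves: tuple[SurvivalCurveData, ...]      # ion curves, ascending LET
    xray_curve: SurvivalCurveData
    truth: dict                                 # label -> dose-axis LQParameters
    spec: SurvivalSimSpec


def ion_label(let_value: float) -> str:
    return f"C-ion-{let_value:g}keV"


def generate_survival_counts(spec: SurvivalSimSpec) -> SimulatedSurvival:
    """Simulate clonogenic assays for the X-ray reference and each ion LET.

    Per dose, each of ``n_replicates`` dishes of ``cells_plated`` cells
    yields Binomial(cells_plated, PE * SF_true) colonies; the SF estimate
    pools replicates: total colonies / (n_replicates * cells_plated * PE),
    truncated at 1.  Its standard error is the pooled binomial one (with a
    +1/2 continuity adjustment so it is never zero).  Doses with zero total
    colonies are excluded with a warning — SF = 0 has no logarithm.
    Identical spec (including seed) reproduces identical output.
    """
    rng = np.random.default_rng(spec.seed)
    qualities = [(XRAY_LABEL, spec.xray_let)] + [
        (ion_label(L), float(L)) for L in spec.let_grid
    ]
    pe = spec.plating_efficiency
    n_tot = spec.n_replicates * spec.cells_plated
    curves: list[SurvivalCurveData] = []
    truth: dict[str, LQParameters] = {}
    for label, let_value in qualities:
        params = spec.true_params(let_value)
        truth[label] = params
        pts = []
        for d in spec.doses:
            sf_true = math.exp(-(params.alpha * d + params.beta * d * d))
            colonies = rng.binomial(spec.cells_plated, pe * sf_true, size=spec.n_replicates)
            total = int(colonies.sum())
            if total == 0:
                warnings.warn(
                    f"{label}: zero colonies at dose {d:g} Gy — point excluded",
                    stacklevel=2,
                )
                continue
            sf_hat = min(total / (n_tot * pe), 1.0)
            p_adj = (total + 0.5) / (n_tot + 1.0)   # keeps the error strictly positive
            sf_err = math.sqrt(p_adj * (1.0 - p_adj) / n_tot) / pe
            pts.append(SurvivalPoint(exposure=float(d), sf=sf_hat, sf_err=sf_err))
        curve = SurvivalCurveData(
            label=label, let_value=let_value, axis="dose", points=tuple(pts)
        )
        curves.append(curve)
    xray = curves[0]
    ions = tuple(curves[1:])
    return SimulatedSurvival(curves=ions, xray_curve=xray, truth=truth, spec=spec)


def ground_truth_dabble(
    spec_s: SurvivalSimSpec,
    spec_g: GValueSimSpec,
    config: DecompositionConfig = DecompositionConfig(),
    time_point: str = "1ps",
    constants: PhysicalConstants = PhysicalConstants(),
) -> list[DabbleResult]:
    """Closed-form DABBLE per ion LET from the generating parameters.

    The dose->radical map at LET L is N = c(L) * D with c = (G(L,t)/100)/e,
    so the true radical-axis coefficients are alpha/c and beta/c^2; no
    fitting or noise enters.  Results are ordered by LET and carry the true
    dose-axis RBE.
    """
    xray_dose = spec_s.true_params(spec_s.xray_let)
    c_x = (spec_g.g(spec_s.xray_let, time_point) / 100.0) / constants.elementary_charge
    xray_rad = LQParameters(
        alpha=xray_dose.alpha / c_x, beta=xray_dose.beta / c_x**2, axis="radicals"
    )
    out: list[DabbleResult] = []
    for L in sorted(spec_s.let_grid):
        ion_dose = spec_s.true_params(L)
        c = (spec_g.g(L, time_point) / 100.0) / constants.elementary_charge
        ion_rad = LQParameters(
            alpha=ion_dose.alpha / c, beta=ion_dose.beta / c**2, axis="radicals"
        )
        rbe = rbe_at_level(xray_dose, ion_dose, config.survival_level)
        out.append(
            dabble(
                ion_rad,
                xray_rad,
                config,
                let_value=float(L),
                time_point=time_point,
                rbe=rbe,
            )
        )
    return out
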
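"""G-values of OH radicals and the dose -> radical-count axis transform.

The G value is the radiation-chemical yield: the number of OH radicals
produced per 100 eV of absorbed energy.  It depends on LET (denser tracks
mean more radical-radical recombination, hence lower yields) and on the
chemical-phase sampling time: 1 ps, right after radical formation, and
100 ns, by which radical-radical reactions have largely subsided.  The LET
dependence is much stronger at 100 ns.

A dose D (Gy = J/kg) deposited in water of unit density produces

    N_OH = (G / 100) * (D / e)   radicals per liter,

with e the elementary charge converting eV to J.  The per-kilogram and
per-liter counts coincide for unit-density water.  The default e is the
rounded 1.6e-19 C commonly used in the field; a CODATA switch is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .errors import (
    AxisMismatchError,
    DomainError,
    MissingDataError,
    TableRangeError,
    ValidationError,
)
from .lq import SurvivalCurveData, SurvivalPoint

TIME_POINTS = ("1ps", "100ns")

ELEMENTARY_CHARGE = 1.6e-19          # J/eV, rounded convention
ELEMENTARY_CHARGE_CODATA = 1.602176634e-19


@dataclass(frozen=True)
class PhysicalConstants:
    """Unit-conversion constants; ``codata()`` selects the exact charge."""

    elementary_charge: float = ELEMENTARY_CHARGE

    @classmethod
    def codata(cls) -> "PhysicalConstants":
        return cls(elementary_charge=ELEMENTARY_CHARGE_CODATA)


@dataclass(frozen=True)
class GValueEntry:
    let_value: float      # keV/um
    time_point: str       # "1ps" or "100ns"
    g_value: float        # species per 100 eV

    def __post_init__(self) -> None:
        if not (np.isfinite(self.let_value) and self.let_value > 0):
            raise ValidationError(f"let_value must be > 0, got {self.let_value}")
        if self.time_point not in TIME_POINTS:
            raise ValidationError(
                f"time_point must be one of {TIME_POINTS}, got {self.time_point!r}"
            )
        if not (np.isfinite(self.g_value) and self.g_value > 0):
            raise ValidationError(f"g_value must be > 0, got {self.g_value}")


class NonMonotoneGTableWarning(UserWarning):
    """A G-value table increases with LET somewhere (physically suspect)."""


@dataclass(frozen=True)
class GValueTable:
    """G(OH) indexed by LET and chemical-phase time point.

    Per time point, LET values must be unique; G is expected to decrease
    (non-strictly) with LET.  Violations of monotonicity warn by default and
    raise in ``strict`` mode, since simulated tables may wiggle slightly.
    """

    entries: tuple[GValueEntry, ...]
    provenance: str = ""
    strict: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        entries = tuple(
            e if isinstance(e, GValueEntry) else GValueEntry(*e) for e in self.entries
        )
        object.__setattr__(self, "entries", entries)
        if not entries:
            raise ValidationError("GValueTable needs at least one entry")
        for tp in self.time_points():
            lets = [e.let_value for e in entries if e.time_point == tp]
            if len(set(lets)) != len(lets):
                raise ValidationError(f"duplicate LET values at time point {tp!r}")
        bad = self.monotonicity_violations()
        if bad:
            msg = "; ".join(
                f"{tp}: G rises from LET {l1:g} to {l2:g}" for tp, l1, l2 in bad
            )
            if self.strict:
                raise ValidationError(f"non-monotone G table: {msg}")
            warnings.warn(f"non-monotone G table: {msg}", NonMonotoneGTableWarning)

    def time_points(self) -> tuple[str, ...]:
        return tuple(tp for tp in TIME_POINTS if any(e.time_point == tp for e in self.entries))

    def lets(self, time_point: str) -> np.ndarray:
        arr = np.array(
            sorted(e.let_value for e in self.entries if e.time_point == time_point)
        )
        if arr.size == 0:
            raise MissingDataError(f"no entries at time point {time_point!r}")
        return arr

    def gvalues(self, time_point: str) -> np.ndarray:
        rows = sorted(
            ((e.let_value, e.g_value) for e in self.entries if e.time_point == time_point)
        )
        if not rows:
            raise MissingDataError(f"no entries at time point {time_point!r}")
        return np.array([g for _, g in rows])

    def monotonicity_violations(self) -> list[tuple[str, float, float]]:
        """(time_point, LET_i, LET_i+1) pairs where G increases with LET."""
        out = []
        for tp in self.time_points():
            lets = self.lets(tp)
            gs = self.gvalues(tp)
            for i in range(len(lets) - 1):
                if gs[i + 1] > gs[i] * (1 + 1e-12):
                    out.append((tp, float(lets[i]), float(lets[i + 1])))
        return out


def interpolate_g(
    table: GValueTable,
    let_value: float,
    time_point: str,
    extrapolate: bool = False,
) -> float:
    """G at an arbitrary LET, linear in (log LET, G).

    Table LETs are returned exactly.  Outside the tabulated range the call
    raises unless ``extrapolate`` is set, in which case the end segment's
    line is extended.
    """
    if time_point not in TIME_POINTS:
        raise MissingDataError(f"unknown time point {time_point!r}")
    if not (np.isfinite(let_value) and let_value > 0):
        raise DomainError(f"let_value must be > 0, got {let_value}")
    lets = table.lets(time_point)
    gs = table.gvalues(time_point)
    lo, hi = lets[0], lets[-1]
    if not (lo <= let_value <= hi) and not extrapolate:
        raise TableRangeError(
            f"LET {let_value:g} outside tabulated range [{lo:g}, {hi:g}] at {time_point}"
        )
    if len(lets) == 1:
        return float(gs[0])
    x = np.log(lets)
    q = np.log(let_value)
    if q <= x[0]:
        slope = (gs[1] - gs[0]) / (x[1] - x[0])
        return float(gs[0] + slope * (q - x[0]))
    if q >= x[-1]:
        slope = (gs[-1] - gs[-2]) / (x[-1] - x[-2])
        return float(gs[-1] + slope * (q - x[-1]))
    return float(np.interp(q, x, gs))


def dose_to_radicals(
    g_value: float, dose, constants: PhysicalConstants = PhysicalConstants()
):
    """OH radicals per liter produced by ``dose`` Gy at yield ``g_value``.

    N = (G/100) * (D/e); linear in both arguments.  ``dose`` may be an array.
    """
    if not (np.isfinite(g_value) and g_value > 0):
        raise DomainError(f"g_value must be > 0, got {g_value}")
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise DomainError(f"dose must be finite and >= 0, got {dose}")
    out = (g_value / 100.0) * (d / constants.elementary_charge)
    return float(out) if np.isscalar(dose) or d.ndim == 0 else out


def transform_curve(
    curve: SurvivalCurveData,
    table: GValueTable,
    time_point: str,
    constants: PhysicalConstants = PhysicalConstants(),
    extrapolate: bool = False,
) -> SurvivalCurveData:
    """Re-express a dose-axis survival curve on the OH-radical-count axis.

    Each point's dose is replaced by the radical count it produces at the
    curve's LET; surviving fractions are untouched and ordering is preserved
    (the map is monotone).
    """
    if curve.axis != "dose":
        raise AxisMismatchError(f"curve {curve.label!r} is already on axis {curve.axis!r}")
    g = interpolate_g(table, curve.let_value, time_point, extrapolate=extrapolate)
    pts = tuple(
        SurvivalPoint(
            exposure=dose_to_radicals(g, p.exposure, constants),
            sf=p.sf,
            sf_err=p.sf_err,
        )
        for p in curve.points
    )
    return SurvivalCurveData(
        label=curve.label, let_value=curve.let_value, axis="radicals", points=pts
    )


def make_gvalue_table(
    rows: Iterable[tuple[float, str, float]], provenance: str = "", strict: bool = False
) -> GValueTable:
    """Build a table from (let, time_point, g) rows."""
    return GValueTable(
        entries=tuple(GValueEntry(*r) for r in rows), provenance=provenance, strict=strict
    )
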
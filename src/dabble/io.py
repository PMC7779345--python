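"""Delimited-table readers/writers, run configuration and the full pipeline.

Formats (CSV or TSV, sniffed from the header line; header row required):

* survival tables — ``label, let_kev_um, axis, exposure, sf, sf_err``
  with axis in {dose, radicals}; sf_err optional/empty;
* G-value tables — ``let_kev_um, time_point, g_value`` with time_point in
  {1ps, 100ns};
* DABBLE output — ``let_kev_um, time_point, n_star, df_c, df_xi, dabble, rbe``;
* ground truth — ``let_kev_um, alpha_true, beta_true, g_1ps, g_100ns,
  dabble_true_1ps, dabble_true_100ns``.

``run_pipeline`` ties the stages together: read tables, fit each curve on
the dose axis, transform to the radical axis at a time point, re-fit,
compute DABBLE and RBE per LET, write the output table and best-effort
diagnostic plots.  Every output number is reproducible by calling the
module operations directly; the CLI adds no arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .decompose import (
    DabbleResult,
    DecompositionConfig,
    dabble_let_profile,
    results_to_records,
)
from .errors import CurveProcessingError, MissingDataError, ParseError, ValidationError
from .lq import SurvivalCurveData, evaluate_sf, fit_lq, make_curve
from .radicals import (
    TIME_POINTS,
    GValueTable,
    PhysicalConstants,
    make_gvalue_table,
    transform_curve,
)

log = logging.getLogger("dabble")

SURVIVAL_COLUMNS = ["label", "let_kev_um", "axis", "exposure", "sf", "sf_err"]
GVALUE_COLUMNS = ["let_kev_um", "time_point", "g_value"]
FLOAT_FMT = "%.10g"


def _read_frame(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    # sep=None sniffs comma vs tab from the file itself
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path: Path, allow_nan: bool = False) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if not allow_nan and (vals.isna()).any():
        # +2: one for the header, one for 1-based numbering
        line = int((vals.isna()).idxmax()) + 2
        raise ParseError(f"{path}: non-numeric or empty {col!r} on line {line}")
    if allow_nan and bad.any():
        line = int(bad.idxmax()) + 2
        raise ParseError(f"{path}: non-numeric {col!r} on line {line}")
    return vals


def read_survival_table(path: str | Path) -> list[SurvivalCurveData]:
    """Parse a survival table into curves grouped by (label, LET, axis).

    Rows are validated individually; the first offending row is reported
    with its 1-based file line number.
    """
    path = Path(path)
    df = _read_frame(path, SURVIVAL_COLUMNS[:5])
    if "sf_err" not in df.columns:
        df["sf_err"] = np.nan
    let = _numeric(df, "let_kev_um", path)
    exposure = _numeric(df, "exposure", path)
    sf = _numeric(df, "sf", path)
    sf_err = _numeric(df, "sf_err", path, allow_nan=True)
    for i in df.index:
        line = int(i) + 2
        if not 0.0 < sf[i] <= 1.0:
            raise ParseError(f"{path}: sf={sf[i]} outside (0, 1] on line {line}")
        if exposure[i] < 0:
            raise ParseError(f"{path}: negative exposure on line {line}")
        if let[i] <= 0:
            raise ParseError(f"{path}: non-positive let_kev_um on line {line}")
        if df.at[i, "axis"] not in ("dose", "radicals"):
            raise ParseError(f"{path}: bad axis {df.at[i, 'axis']!r} on line {line}")
    curves = []
    for (label, let_v, axis), grp in df.groupby(
        ["label", "let_kev_um", "axis"], sort=False
    ):
        errs = [None if pd.isna(e) else float(e) for e in sf_err[grp.index]]
        try:
            curves.append(
                make_curve(
                    str(label),
                    float(let_v),
                    str(axis),
                    exposure[grp.index].tolist(),
                    sf[grp.index].tolist(),
                    errs,
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{path}: curve {label!r}: {exc}") from exc
    return curves


def write_survival_table(curves: Sequence[SurvivalCurveData], path: str | Path) -> None:
    rows = [
        {
            "label": c.label,
            "let_kev_um": c.let_value,
            "axis": c.axis,
            "exposure": p.exposure,
            "sf": p.sf,
            "sf_err": p.sf_err,
        }
        for c in curves
        for p in c.points
    ]
    pd.DataFrame(rows, columns=SURVIVAL_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_gvalue_table(path: str | Path, strict: bool = False) -> GValueTable:
    """Parse a G-value table; non-monotone G(LET) warns unless ``strict``."""
    path = Path(path)
    df = _read_frame(path, GVALUE_COLUMNS)
    let = _numeric(df, "let_kev_um", path)
    g = _numeric(df, "g_value", path)
    for i in df.index:
        line = int(i) + 2
        tp = str(df.at[i, "time_point"])
        if tp not in TIME_POINTS:
            raise ParseError(f"{path}: bad time_point {tp!r} on line {line}")
        if g[i] <= 0:
            raise ParseError(f"{path}: non-positive g_value on line {line}")
        if let[i] <= 0:
            raise ParseError(f"{path}: non-positive let_kev_um on line {line}")
    rows = [
        (float(let[i]), str(df.at[i, "time_point"]), float(g[i])) for i in df.index
    ]
    try:
        return make_gvalue_table(rows, provenance=str(path), strict=strict)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_gvalue_table(table: GValueTable, path: str | Path) -> None:
    rows = [
        {"let_kev_um": e.let_value, "time_point": e.time_point, "g_value": e.g_value}
        for e in table.entries
    ]
    pd.DataFrame(rows, columns=GVALUE_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML-loadable, CLI-overridable."""

    survival_table: str = ""
    gvalue_table: str = ""
    time_point: str = "1ps"
    k: float = 0.76
    survival_level: float = 0.1
    xray_label: str = "200kVp-Xray"
    constants: str = "rounded"          # conventional 1.6e-19 vs "codata"
    out_table: str = "dabble_profile.csv"
    plot_dir: Optional[str] = None
    strict_gtable: bool = False
    weighting: str = "none"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.time_point not in TIME_POINTS:
            raise ValidationError(f"time_point must be one of {TIME_POINTS}")
        if self.constants not in ("rounded", "codata"):
            raise ValidationError("constants must be 'rounded' or 'codata'")
        DecompositionConfig(k=self.k, survival_level=self.survival_level)  # validates

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def with_overrides(self, **overrides) -> "RunConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})

    @property
    def physical_constants(self) -> PhysicalConstants:
        return (
            PhysicalConstants.codata() if self.constants == "codata" else PhysicalConstants()
        )

    @property
    def decomposition(self) -> DecompositionConfig:
        return DecompositionConfig(k=self.k, survival_level=self.survival_level)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute the full dose -> radicals -> DABBLE analysis.

    Writes the DABBLE table to ``config.out_table`` and, when ``plot_dir``
    is set, survival-curve plots on both axes plus a DABBLE/RBE-vs-LET
    panel.  Plotting is best-effort and never fails the run; the numeric
    table is the contract.  Raises CurveProcessingError (after writing
    nothing) if any curve fails.
    """
    logging.basicConfig(level=config.log_level)
    log.info(
        "pipeline config: time_point=%s k=%g survival_level=%g e=%.10g weighting=%s",
        config.time_point,
        config.k,
        config.survival_level,
        config.physical_constants.elementary_charge,
        config.weighting,
    )
    curves = read_survival_table(config.survival_table)
    table = read_gvalue_table(config.gvalue_table, strict=config.strict_gtable)
    xray = [c for c in curves if c.label == config.xray_label]
    if not xray:
        raise MissingDataError(
            f"X-ray reference label {config.xray_label!r} not found in "
            f"{config.survival_table}"
        )
    ions = [c for c in curves if c.label != config.xray_label]
    for c in curves:
        fit = fit_lq(c, config.weighting)
        err = (
            np.sqrt(np.diag(fit.covariance)) if fit.covariance is not None else (np.nan,) * 2
        )
        log.info(
            "dose-axis fit %s (LET %g): alpha=%.6g +/- %.2g, beta=%.6g +/- %.2g",
            c.label, c.let_value, fit.alpha, err[0], fit.beta, err[1],
        )
    results = dabble_let_profile(
        ions,
        xray[0],
        table,
        config.time_point,
        config.decomposition,
        config.physical_constants,
        config.weighting,
    )
    df = pd.DataFrame(results_to_records(results))
    out = Path(config.out_table)
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False, float_format=FLOAT_FMT)
    log.info("wrote %d-row DABBLE table to %s", len(df), out)
    if config.plot_dir is not None:
        try:
            _plots(curves, xray[0], table, results, config)
        except Exception as exc:  # plots are best-effort, numbers are the contract
            log.warning("plot generation failed: %s", exc)
    return df


def _plots(curves, xray_curve, table, results: list[DabbleResult], config: RunConfig) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    plot_dir = Path(config.plot_dir)
    plot_dir.mkdir(parents=True, exist_ok=True)

    for axis_tag, transform in (("dose", False), ("radicals", True)):
        fig, ax = plt.subplots(figsize=(6, 4.5))
        for c in curves:
            cc = (
                transform_curve(c, table, config.time_point, config.physical_constants)
                if transform
                else c
            )
            fit = fit_lq(cc, config.weighting)
            xs = np.linspace(0, cc.exposures.max(), 200)
            ax.plot(xs, evaluate_sf(fit, xs), lw=1)
            ax.plot(cc.exposures, cc.sf, "o", ms=3, label=f"{c.label}")
        ax.set_yscale("log")
        ax.set_xlabel(
            "absorbed dose (Gy)"
            if axis_tag == "dose"
            else f"OH radicals per liter ({config.time_point})"
        )
        ax.set_ylabel("surviving fraction")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(plot_dir / f"survival_{axis_tag}.png", dpi=120)
        plt.close(fig)

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    lets = [r.let_value for r in results]
    ax1.plot(lets, [r.dabble for r in results], "o-")
    ax1.set_xscale("log")
    ax1.set_xlabel("LET (keV/um)")
    ax1.set_ylabel(f"DABBLE at {100 * (1 - config.survival_level):g}% death ({config.time_point})")
    ax2.plot(lets, [r.rbe for r in results], "s-", color="C1")
    ax2.set_xscale("log")
    ax2.set_xlabel("LET (keV/um)")
    ax2.set_ylabel("RBE at 10% survival")
    fig.tight_layout()
    fig.savefig(plot_dir / "dabble_rbe_vs_let.png", dpi=120)
    plt.close(fig)
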
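"""Re-express survival curves on the OH-radical axis and re-fit.

Converts every dose point to the number of OH radicals it produces,
N = (G/100) * (D/e), using the tabulated G(LET, t) at 1 ps and 100 ns, and
re-fits the LQ model on the radical axis.  Because G falls with LET, ion
curves that are spread out on the dose axis collapse toward (and cross)
the X-ray curve on the radical axis — most dramatically at 100 ns.

Outputs: results/survival_radicals_{1ps,100ns}.csv, results/lq_fits_radicals.csv
"""

from pathlib import Path

import pandas as pd

from dabble import (
    fit_lq,
    invert_lq,
    read_gvalue_table,
    read_survival_table,
    transform_curve,
    write_survival_table,
)
from dabble.io import FLOAT_FMT

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    curves = read_survival_table(RESULTS / "survival_table.csv")
    table = read_gvalue_table(RESULTS / "gvalue_table.csv")

    rows = []
    for tp in ("1ps", "100ns"):
        transformed = [transform_curve(c, table, tp) for c in curves]
        write_survival_table(transformed, RESULTS / f"survival_radicals_{tp}.csv")
        for c in transformed:
            fit = fit_lq(c, "inverse_variance")
            rows.append(
                {
                    "label": c.label,
                    "let_kev_um": c.let_value,
                    "time_point": tp,
                    "alpha_per_radical_L": fit.alpha,
                    "beta_per_radical_L2": fit.beta,
                    "n10_per_L": None if fit.alpha + fit.beta == 0 else invert_lq(fit, 0.1),
                }
            )
        n_max = max(p.exposure for c in transformed for p in c.points)
        print(f"{tp}: transformed {len(transformed)} curves; max N_OH = {n_max:.3g} /L")

    df = pd.DataFrame(rows).sort_values(["time_point", "let_kev_um"])
    df.to_csv(RESULTS / "lq_fits_radicals.csv", index=False, float_format=FLOAT_FMT)

    for tp in ("1ps", "100ns"):
        sub = df[(df.time_point == tp) & (df.label != "200kVp-Xray")]
        spread = sub.n10_per_L.max() / sub.n10_per_L.min()
        print(f"{tp}: ion N10 spans a factor {spread:.1f} across LET "
              "(smaller N10 at high LET = more killing per radical)")
    print(f"wrote survival_radicals_*.csv, lq_fits_radicals.csv to {RESULTS}/")


if __name__ == "__main__":
    main()
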
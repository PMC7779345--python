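# dabble

Decomposition of radiation cell killing into direct and indirect action by
re-expressing clonogenic survival curves on an **OH-radical-count axis**.

## The problem

Relative biological effectiveness (RBE) compares radiation qualities at equal
absorbed dose, but absorbed dose ignores track structure: a carbon ion deposits
its energy in a dense column, X-rays spread it homogeneously. The number of OH
radicals produced — the dominant agent of *indirect* action — is a more
quality-aware exposure variable. Putting survival curves of V79 cells on that
axis lets the indirect component of killing be matched between radiations, so
the remainder can be attributed to *direct* action (including quasi-direct
action via the hydration shell).

## The model

Survival follows the linear-quadratic (LQ) model on either axis:

    SF_t(D)    = exp(−(α_D D + β_D D²))            dose axis, D in Gy
    N_OH       = (G/100) · (D/e)                   radicals per liter
    SF_t(N_OH) = exp(−(α_OH N + β_OH N²))          radical axis

with G = G(LET, t) the OH yield per 100 eV at chemical-phase time t (1 ps or
100 ns) and e = 1.6 × 10⁻¹⁹ J/eV. With k the contribution ratio of indirect
action (k = 0.76 for V79 / 200 kVp X-rays), killing splits as

    DF_in(N) = k · (1 − SF_t(N))        SF_in(N) = k·SF_t(N) + (1−k)
    SF_d(N)  = (1−k)·SF_t(N) + k

At the radical count N\* where the ion curve reaches 10% survival (ion death
fraction DF_C = 0.9), the X-ray indirect death fraction DF_XI = DF_in,xray(N\*)
is the indirect share of the ion's killing, and

    DABBLE = (DF_C − DF_XI) / DF_XI

is the ratio of direct to indirect action. For coincident curves it reduces to
(1−k)/k ≈ 0.316.

## Worked example

The `analysis/` scripts run the whole study on synthetic data with known
ground truth (an X-ray reference at LET 9.4 keV/μm plus ten carbon-ion
qualities, 22.5–432 keV/μm, binomial colony-count noise):

```sh
python analysis/01_simulate.py          # survival + G tables + ground truth
python analysis/02_fit_survival.py      # dose-axis LQ fits, D10, RBE vs LET
python analysis/03_transform_radicals.py
python analysis/04_dabble_profile.py    # DABBLE vs LET at 1 ps and 100 ns
```

which prints (seed 0):

```
fitted 11 curves; X-ray D10 = 8.11 Gy
RBE_10% peaks at 4.60 at LET 140 keV/um
1ps: DABBLE range 0.42-5.57, peak at LET 140 keV/um, unimodal; max recovery error 3.7%
100ns: DABBLE range 0.51-51.89, peak at LET 432 keV/um, monotone increasing; max recovery error 3.5%
```

Read: on the 1 ps radical axis DABBLE rises with LET to a maximum near
140 keV/μm and then drops, tracking RBE (overkill); on the 100 ns axis —
after radical–radical recombination has thinned the tracks — DABBLE keeps
rising with LET, i.e. the effectiveness of high-LET ions is carried by direct
action. Tables land in `results/` (e.g. `dabble_profile.csv` with columns
`let_kev_um, time_point, n_star, df_c, df_xi, dabble, rbe`).

The same pipeline is scriptable from the shell:

```sh
dabble simulate --out-dir sim --seed 0
dabble dabble --survival-table sim/survival_table.csv \
    --gvalue-table sim/gvalue_table.csv --time-point 100ns \
    --weighting inverse_variance --out profile.csv
```

## Layout

- `src/dabble/lq.py` — LQ model: evaluate, fit (non-negative weighted least
  squares on ln SF), invert, RBE
- `src/dabble/radicals.py` — G-value tables, log-LET interpolation, dose→radical
  transform
- `src/dabble/decompose.py` — direct/indirect split, DABBLE, LET profiles
- `src/dabble/simulate.py` — synthetic clonogenic assays and G tables with
  analytic ground truth
- `src/dabble/io.py`, `src/dabble/cli.py` — table formats, config, pipeline, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
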
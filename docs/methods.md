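# Methods

## Model and assumptions

Clonogenic survival is linear-quadratic in the exposure variable x:
SF_t(x) = exp(−(αx + βx²)) with α, β ≥ 0, on either the absorbed-dose axis
(x = D, Gy) or the OH-radical-count axis (x = N_OH, radicals per liter).
The radical count produced by a dose D at a quality with OH yield G
(species per 100 eV) is N_OH = (G/100)·(D/e). G values are per-kilogram of
water; we assume unit-density water so per-kilogram and per-liter coincide.
The elementary charge defaults to the rounded 1.6 × 10⁻¹⁹ J/eV conventional
in this literature; `PhysicalConstants.codata()` selects 1.602176634 × 10⁻¹⁹
when exact SI arithmetic is preferred. The axis transform is a pure rescaling
per quality, so α_OH = α_D/c and β_OH = β_D/c² with c = (G/100)/e — an exact
identity we test to 1e-6 relative after a round trip through fitting.

The decomposition assumes (i) a quality-independent contribution ratio k of
indirect action, taken from scavenger experiments (k = 0.76 for V79 cells
under 200 kVp X-rays; we model no LET dependence of k), and (ii) that at
equal N_OH the indirect death fraction is equal across radiation qualities.
Under these, DF_in = k(1 − SF_t), SF_in = k·SF_t + (1−k) (asymptote 1−k:
radicals alone can never kill every cell), SF_d = (1−k)·SF_t + k, and
DABBLE = (DF_C − DF_XI)/DF_XI with DF_C = 1 − survival_level evaluated where
the ion curve crosses the survival level and DF_XI from the X-ray fit at the
same radical count. Quasi-direct action is folded into direct action, not a
separate compartment.

## Fitting

−ln SF is linear in (α, β), so fitting is bounded linear least squares
solved exactly by non-negative least squares (scipy `nnls`) on the design
[x, x²] — no iterative optimizer, no initialization, no convergence
failures in practice. Optional inverse-variance weights use
var(ln SF) ≈ (sf_err/sf)² (delta method). The parameter covariance is
(AᵀWA)⁻¹ for known weights and the residual-scaled unweighted form
otherwise. Radical-axis exposures (~10¹⁷–10¹⁸/L) are rescaled internally to
units of 10¹⁷/L so the normal equations stay well conditioned; reported
parameters are converted back.

Weighted fitting is the package's default analysis choice for clonogenic
data: binomial colony noise is strongly heteroscedastic on the log scale,
and unweighted log-least-squares over-weights the deep survival tail.

## Inversion and degenerate inputs

The iso-effect exposure solves αx + βx² = L with L = ln(1/SF*). We use the
cancellation-free root x = 2L/(α + √(α² + 4βL)), which is exact for β = 0
(reduces to L/α) and numerically stable for arbitrarily small β, so no
small-β threshold is needed. α = β = 0 (a flat curve, the boundary solution
for all-surviving data) is representable but raises a no-solution error on
inversion; k = 0 or N* = 0 makes DABBLE's denominator vanish and raises an
undefined-statistic error. Duplicate exposures are rejected at load.
RBE at a survival level is the ratio of the reference's iso-effect dose to
the test's, computed from each curve's own fit.

## G-value handling

Tables hold G at the two sampled chemical-phase times only (1 ps: onset of
chemistry; 100 ns: radical–radical reactions largely subsided); continuous
G(t) is out of scope. Interpolation between tabulated LETs is linear in
(log LET, G), matching how these curves are plotted and inspected; queries
outside the table range raise unless extrapolation (end-segment extension)
is explicitly enabled. The 200 kVp X-ray reference is an ordinary table row
at its effective LET of 9.4 keV/μm. Tables that rise with LET anywhere are
physically suspect: readers warn by default and error in strict mode.

## Synthetic-data generator

The generator emulates the structure of published V79 carbon-ion survival
measurements and simulated OH yields, with every parameter known:

- **α(LET)** = 0.10 + 1.20·exp(−ln²(LET/140)/(2·0.8²)) per Gy — unimodal in
  log LET, peaking at 140 keV/μm (radiosensitivity maximum before overkill).
  At the X-ray LET this gives α ≈ 0.10/Gy and, with β below, an X-ray
  D10 ≈ 8 Gy, typical of V79 under 200 kVp X-rays.
- **β(LET)** = 0.025·exp(−LET/80) per Gy² — the shoulder shrinks with LET
  and is effectively gone above ~200 keV/μm.
- **G(LET, t)** = g∞ + (g0 − g∞)·exp(−LET/100) per 100 eV with plateaus
  5.5 → 4.2 at 1 ps and 3.0 → 0.1 at 100 ns: a weak LET dependence at 1 ps,
  a strong one at 100 ns (dense tracks recombine most of the OH by 100 ns),
  magnitudes in the range track-chemistry simulations report. The generator
  validates that the 100 ns decline factor strictly exceeds the 1 ps one.
- **Noise**: per dose, each of 3 replicate dishes of 500 plated cells
  (plating efficiency 0.8) yields Binomial(cells, PE·SF) colonies — the
  canonical clonogenic-assay statistic. The pooled SF estimate is
  total/(n·cells·PE), truncated at 1 (a fraction cannot exceed 1); its
  standard error uses a +½ continuity adjustment so it is never zero.
  Doses with zero total colonies are excluded with a warning (SF = 0 has
  no logarithm) rather than continuity-corrected.
- **Design**: 10 ion LETs from 22.5 to 432 keV/μm plus the X-ray reference;
  10 dose levels 0.5–8 Gy shared across qualities.

`ground_truth_dabble` evaluates the entire decomposition in closed form
from the generating α(LET), β(LET) and G(LET, t) — no fitting, no noise —
giving the recovery target for the noisy pipeline. On the fixed-seed suite
the noisy pipeline recovers it within 15% relative error at every LET and
reproduces the two qualitative LET trends (unimodal at 1 ps, peak 140
keV/μm, tracking RBE; monotone increasing at 100 ns).

What the generator does **not** emulate: track-structure chemistry itself
(G tables are parametric stand-ins, not physics), inter-experiment
systematics, over-dispersion beyond binomial, cell-cycle structure (the
underlying survival data are asynchronous populations; cycle dependence is
deliberately out of scope), or the true dispersion of the historical
measurements. Passing recovery tests therefore validates the pipeline's
statistics, not any claim about real beam data.

## Numerical and design choices

- Fit linearized on ln SF: standard radiobiology practice and it makes the
  problem exactly solvable; α, β constrained non-negative since the model
  presumes killing.
- The DABBLE profile re-fits the X-ray reference on the radical axis per
  time point (its G differs at 1 ps vs 100 ns).
- Per-curve failures in a batch are collected and raised together with the
  partial results, never silently dropped; the CLI reports each and exits
  nonzero.
- Output tables are written with `%.10g` floats so identical inputs, config
  and seed regenerate byte-identical files.
- Plot generation is best-effort and never affects exit status; the numeric
  tables are the contract.
- DABBLE uncertainty propagation from fit covariances is not implemented;
  the fit covariances themselves are exposed for callers who need it.

## Problem sizes

The shipped analysis and test suite use the 10-LET, 10-dose, 3-replicate,
500-cell design throughout: large enough that fitted parameters carry a few
percent error and the DABBLE recovery band (15%) is meaningfully exercised,
small enough that the whole pipeline runs in seconds.

## Known limitations

- k is a single scalar; any LET or dose dependence of the indirect
  contribution is outside the model.
- Only the two sampled time points are first-class; no interpolation in
  time.
- The LQ form is assumed throughout; multi-target, repair-misrepair and
  microdosimetric-kinetic alternatives are non-goals.
- Survival levels far from 0.1 are allowed by configuration, but k was
  measured at lethality levels comparable to 10% survival; extrapolating
  the decomposition to extreme levels stretches assumption (i).
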
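# Methods

`aqemu` implements a desk-scale version of an emulator-based air-quality
health assessment: a cheap surrogate stands in for a chemical transport
model (CTM), per-grid-cell Gaussian-process (GP) emulators learn the
mapping from five sectoral emission scalings to annual pollutant metrics,
and the emulated fields drive an exposure–response burden calculation and
a full-factorial search for emission configurations that attain
air-quality targets.

## The synthetic domain and surrogate simulator

The domain is a flat set of `n_cells` grid cells (no geometry — only
population weighting and admin aggregation matter). Cells carry a
three-level admin hierarchy (prefecture → province → region, each unit
belonging to exactly one parent) plus a reporting-only "bay-area" subset
of one province. Population is log-normal across cells (median 5×10⁵,
σ=1); adult age fractions (25–80+ in 5-year brackets) perturb a fixed
national template by ±5% log-normal jitter, always summing to < 1 per
cell. The under-25 remainder carries zero risk for both pollutants.

The surrogate maps a scenario `s ∈ [0, 1.5]⁵` (scaling factors for the
residential RES, industrial IND, transport TRA, agricultural AGR and
power-generation ENE sectors; 1.0 = baseline year) to two per-cell
metrics:

* **PM2.5 (annual mean, μg m⁻³)** — `base_i + Σ_k c_ik · s_k^{p_ik}`,
  with `c_ik ≥ 0` and per-cell exponents `p_ik ∈ [0.92, 1.08]`
  (`pm_nonlinearity` scales this spread; 0 gives an exactly linear
  response). The response is non-decreasing in every sector by
  construction, and because the baseline contribution of sector k is
  exactly `c_ik`, the per-cell coefficient columns are rescaled once so
  the national population-weighted sector shares at baseline equal the
  configured targets exactly (defaults: RES 21%, IND 28%, TRA 4%, AGR 3%,
  ENE 2%, other sources 42%).
* **O3 (6mDM8h, ppb)** — background plus a per-sector quadratic
  `a_ik·s_k + q_ik·s_k²` and one signed IND×TRA interaction per cell.
  A configurable fraction of cells (default 20%) is "VOC-limited": their
  NOx-heavy sector terms (ENE, TRA, AGR) are decreasing on [0, 1], so
  reducing those emissions *raises* O3 locally — the titration behaviour
  the attainment analysis must cope with. IND and RES terms are always
  increasing (their removal always lowers O3).

Simulator noise defaults to 0 (a CTM is deterministic per configuration).
Site observations are `truth × province bias + Gaussian noise` at a
seeded random subset of cells, so the tuning step can recover the bias
factors exactly in the noise-free case.

What the surrogate does *not* emulate: atmospheric transport and
chemistry, seasonality, spatial correlation between neighbouring cells,
emission-inventory structure, or real geography. Passing tests therefore
demonstrate that the pipeline machinery (design → emulation → tuning →
burden → attainment) is correct and internally consistent on a system
with the assumed response structure — not that a GP emulator would reach
the same accuracy on a real CTM.

## Exposure metrics

The chronic ozone metric (6mDM8h) follows the standard recipe: 24
trailing 8-hour rolling means anchored at each start hour (windows may
run into the next day; year-end windows are truncated), the daily maximum
of those, then 12 six-month means of the daily maxima — one window
starting at each calendar month — and the maximum of the 12. Six-month
windows wrap across the year boundary within the same year's data by
default (`wrap=False` truncates at December instead); wrapping is the
only way to obtain 12 distinct windows from a single year. Both variants
are checked against brute-force enumeration in the tests. Exposure is
always the population-weighted concentration `Σ P_i C_i / Σ P_i`; ozone
standards given in μg m⁻³ convert at 1 ppb ≈ 2 μg m⁻³.

## Model evaluation and tuning

Model skill uses the normalized mean bias factor and normalized mean
absolute error factor (piecewise-symmetric forms: normalized by ΣO when
mean(M) ≥ mean(O), by ΣM otherwise), which are antisymmetric under
swapping model and observations and satisfy NMAEF ≥ |NMBF|.

Tuning multiplies modelled fields by `mean(observed)/mean(modelled)` per
prefecture where sites exist, per province for unobserved prefectures,
and 1 (with a logged warning) for provinces with no sites at all. The
statistic matched is the unit mean; tuning is fitted once at baseline and
applied to every scenario prediction, since emulators are trained on raw
(untuned) simulator output. Tuning is a fixed point: refitting on tuned
fields returns unit factors.

## Emulation

One emulator per (cell, pollutant): a Yeo–Johnson power transform fitted
to the training inputs (per dimension, standardized), then a GP with
kernel `const × Matern(ν=5/2, anisotropic) + white noise`. Outputs are
left untransformed (`normalize_y` centres/scales internally).
Hyperparameters maximize the marginal likelihood with 5 seeded restarts;
per-cell seeds derive from (set seed, cell, pollutant) so results are
independent of fit order. Numerical choices: length-scale bounds
(0.1, 1000) — near-linear targets want very long length scales and a
tight upper bound measurably inflates extrapolation error at lattice
corners; noise variance bounded in (1e-10, 1e-2) as a stability jitter.
Predictions outside the [0, 1.5] training box are refused rather than
extrapolated. Predictive standard deviations are computed and exposed but
not propagated into the health uncertainty intervals, which cover health
parameters only.

Training/test designs are maximin Latin hypercubes (default 50 train,
5 test, independently seeded): each dimension is stratified into n
equal bins sampled exactly once, and among `n_candidates` (default 100)
candidate hypercubes drawn from one seeded stream the design with the
largest minimum pairwise distance wins (first candidate on ties). A
candidate search was preferred over exchange optimization: it is simple,
deterministic, nested in the candidate count, and ample at n = 50.

Persistence stores kernel hyperparameters, transformer state and training
data as JSON; reloading rebuilds each GP with the optimizer disabled,
which reproduces bit-identical predictions.

## Health impact assessment

PM2.5 uses the GEMM (Global Exposure Mortality Model) for non-accidental
mortality (NCD+LRI) with age-bracket parameters:

    z  = max(0, PM2.5 − 2.4 μg m⁻³)
    RR(z, age) = exp( θ_age · ln(1 + z/α) / (1 + exp((μ − z)/ν)) )
    PAF = P_age · (1 − 1/RR)

O3 uses a log-linear COPD hazard of 1.06 (95UI 1.02–1.10) per 10 ppb
above a 35.7 ppb counterfactual: `PAF = P·(1 − exp(−z·ln(HR)/10))`. The
exponent is negative so that the attributable fraction is non-negative
and increasing in z; "log" is the natural logarithm throughout (a base-10
reading would break the per-10-ppb hazard semantics). O3 burden is
applied to all adult brackets with bracket-specific COPD baseline rates,
mirroring the PM2.5 age handling.

Burden: MORT/YLL/YLD = PAF × baseline rate per (cell, age bracket),
DALYs = YLL + YLD, rates per 100,000 people. Aggregation sums cells
nationally, per region and for the bay-area subset (reported standalone
but contained in its region, so national totals never double-count).

95% uncertainty intervals are propagated by bound evaluation: the whole
pipeline is run at the all-lower, central and all-upper tuples of
(θ, HR, baseline-rate) triples. Every stage is monotone in each of these
parameters, so the output triple is ordered; Monte-Carlo propagation was
not needed for the shipped parameter sets. Age-fraction uncertainty is
not propagated — the synthetic age fractions carry no interval.

The packaged GEMM table (`data/gemm_params_synthetic.csv`) is a synthetic
fixture: the published all-age parameter set (θ=0.1430, α=1.6 μg m⁻³,
μ=15.5 μg m⁻³, ν=36.8 μg m⁻³) with a smooth, declining age modifier and
symmetric θ intervals. A real application would substitute the published
cohort-derived age table in the same layout.

## Scenario scan and attainment

The scan lattice is the Cartesian product of 8 levels
{0.0, 0.2, …, 1.4} per sector (32,768 configurations; the level set is
chosen so the count is 8⁵ — the all-ones baseline is not a lattice point
and is evaluated separately). `evaluate_grid` computes tuned national,
regional and bay-area population-weighted exposures per scenario (and
optionally national mortality) through either the emulator set or the
surrogate directly; the latter is the enumeration oracle used in testing.
Attainment at a target is the subset with scoped exposure ≤ threshold;
the "mean emission reduction" for sector k is the arithmetic mean of
(1 − s_k)·100% over that subset.

On the exactly-linear surrogate the emulator-driven attaining set at the
national 35 μg m⁻³ target is identical to direct surrogate enumeration.
At tighter thresholds a handful of knife-edge configurations whose true
national exposure lies within the emulators' ~0.02 μg m⁻³ lattice-corner
error of the threshold can flip; counts there still agree to well under
0.5% of the lattice.

## Problem sizes

The desk-scale study uses 100 cells × 2 pollutants (200 GP emulators),
50 training and 5 test runs, and the full 32,768-configuration scan;
unit tests use a 40-cell domain with 8-cell emulator subsets. These sizes
keep every stage to minutes on a single CPU while leaving all statistical
structure (shares, titration, admin fallback, UI ordering) exercised.

## Known limitations

* The surrogate's smooth low-order response is far easier to emulate than
  a real CTM; held-out R² here (≈ 0.99999) should not be read as expected
  CTM performance, only as consistency with the reported ~0.999 level.
* GP predictions are not constrained to be monotone; monotonicity holds
  empirically at the achieved accuracy but is not guaranteed.
* Attainment equivalence degrades for thresholds crossing densely
  populated parts of the exposure distribution (see above).
* No spatial correlation between cells: per-cell independent fits cannot
  be compared against spatially pooled emulation strategies here.
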
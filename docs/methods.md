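# Methods

## Models and assumptions

**Retention–depth.** The retained fraction after needle withdrawal is
modelled as `R(d) = 1 − exp(−β·dⁿ)` with depth `d` in mm measured from the
tissue/gel surface along the needle axis. The mechanistic reading is a
sealing force `N(d) = k·dⁿ` opposing reflux along the track and a retention
sensitivity α per force unit, lumped as `β = α·k`; β therefore absorbs
tissue viscosity and compliance, needle geometry and protocol (speed,
pauses) and must be re-estimated whenever any of those change. The sealing
exponent `n` defaults to 1 (the linear case used throughout); the power
form stays evaluable but is not part of default fitting. β carries units
1/mmⁿ when n ≠ 1.

**Hypoperfusion–volume.** The graft is treated as a perfect avascular
sphere. Oxygen tension decays mono-exponentially with distance from the
nearest capillary, `pO2(L) = pO2_cap·exp(−L/λ)` (defaults 50 mmHg, λ =
30 µm, critical threshold 5 mmHg). Rather than thresholding that law, the
geometry adopts a fixed oxygenated margin of 100 µm: the shell within the
margin of the graft surface is supplied, the core is hypoperfused, giving
`HypoR(r) = ((r − margin)/r)³`, clamped to exactly 0 for `r ≤ margin`
(continuous at the boundary, strictly increasing beyond, limit 1). The
volume parameterisation goes through `r = (3v/4π)^(1/3)`; the two forms are
the same function and the package asserts their equivalence to 1e−12. The
diffusion-derived distance at which pO2 hits the critical threshold,
`λ·ln(pO2_cap/pO2_critical)` ≈ 69 µm at defaults, is exposed separately
(`diffusion_margin`) and never silently substituted for the 100-µm working
margin. Early growth is `G(v) = Gmax·(1 − HypoR(v))^γ`; γ defaults to 3,
with model selection available for γ ∈ {1, 2, 3, free}.

Canonical internal units are µm and µm³ (1 nL = 10⁶ µm³, 1 µL = 10⁹ µm³);
public converters handle nL/µL. This avoids the unit trap in the
volume-form HypoR expression, which silently mixes mm³ and µm.

## Estimation

Fits minimise unweighted ordinary least squares on the fraction/readout
scale (no weighting scheme is imposed). The single-parameter fits (β;
margin in hypoperfusion-readout mode) scan ~32 log-spaced starts and polish
the best bracket with bounded Brent to xatol 1e−12; the (Gmax, γ) fit runs
bounded trust-region least squares from 8 log-spaced starts per free
parameter, keeping the best optimum. With γ fixed the Gmax estimate is the
closed-form OLS projection. Bounds: β ∈ [0, 50] 1/mm, γ ∈ [10⁻³, 25],
Gmax ∈ (0, 10⁶], margin ∈ [1, 1000] µm. Estimates at a bound and
non-convergence are flagged in the result, never silent. When every volume
lies below V_th the growth model is flat: Gmax is identified as the mean
readout and γ is reported NaN with a `gamma_unidentifiable` flag.

Raw imaging signals are converted to fractions by dividing by an explicit,
user-supplied delivered-dose reference (required in signal mode); no
implicit normalisation is attempted. A boolean `qc_pass` column is honoured
as-is; there is no automatic outlier rejection.

**Bootstrap.** Confidence intervals are percentile intervals from
`n_boot = 1000` nonparametric resamples of sites (rows), stratified by
depth/volume group whenever every group has ≥ 2 rows (preserving the
design), plain row resampling otherwise. Resample refits warm-start from
the full-data estimate (one start); the objective is identical to the
primary fit, so this only removes redundant grid scans. All randomness
comes from one `numpy` generator seeded by `FitConfig.seed`; identical seed
and data give bit-identical intervals. More than 20% failed resample fits
raises with diagnostics. `n_boot = 0` skips the bootstrap (simulation
ladders, model-selection candidates). Percentile intervals at these small
designs (n ≈ 23 sites in three groups) run slightly below nominal: measured
coverage of a nominal 95% interval is ~90–91% in the package's own
simulation, which the acceptance band anticipates.

**Diagnostics.** R² is `1 − SS_res/SS_tot` about the observed mean,
reported NaN (not −∞) when the observations have zero variance with
nonzero residuals; MAE and RMSE are on the observation scale. The residual
trend test is a two-sided Spearman rank correlation of residuals against
the predictor: exact permutation p-value for n < 10 (vectorised Pearson on
ranks over all n! permutations; average ranks under ties), scipy's
large-sample approximation for n ≥ 10; constant residuals give ρ = 0,
never flagged. Flagging threshold p < 0.05.

**Model selection.** Candidate exponents are ranked by (residuals
untrended, fewer free parameters, lower RMSE) — i.e. keep the simplest
model whose residuals show no volume dependence, tie-broken by fit error.
Per-candidate failures are recorded and sort last rather than aborting the
comparison.

**Sensitivity.** `sensitivity_sweep` scales each parameter through
[1 − f, 1 + f] (default f = 0.20) over a prediction grid and returns a tidy
table for plotting.

## Planner

`max_volume_for_hypoperfusion_budget` inverts the cube law analytically
(`r = margin/(1 − h^(1/3))`). `pulse_elevation_schedule` splits the dose
into equal boluses at linearly spaced depths from deep to shallow, with a
pause after every step but the last and a final dwell; defaults (0.1
µL/min, 20-s pauses, 5-min dwell) reproduce the validated
superficial-cortex protocol of five 20-nL steps at 0.5–0.1 mm. When the
total volume does not divide evenly the remainder goes to the deepest step,
which has the highest predicted retention. `plan_report` attaches per-step
retention R(dᵢ), a volume-weighted aggregate Σ(vᵢ/V)·R(dᵢ) — labelled in
the output as a first-order model estimate, since no aggregation rule has
been validated against pulse-elevation data — and HypoR of the pooled
total volume.

## Graft-interface analytics

Proximity to the implantation site uses the planar (x, y) distance to the
site centre, boundary-inclusive at the default 120-µm radius, matching the
practice of drawing a circle on 2D projections; z is ignored. Per-day
counts are distinct cell ids inside the circle; duplicate (cell, day) rows
are an error. Migration metrics are 3D: path length sums Euclidean step
lengths between consecutive sessions, net displacement is first-to-last;
single-point tracks return zeros with a flag. ROI traces are
background-subtracted (negative corrected values clipped to 0 and
flagged) and normalised by either an explicit baseline or the final-day
group mean — appropriate when activity has returned to rest by the end of
the window; the rule is an explicit parameter because no canonical
normalisation exists. The automatic track linker is opt-in convenience for
synthetic or lightly curated data: consecutive days are matched by
minimal-total-distance assignment (Hungarian) among pairs within
`max_step`, unmatched points start new identities, and matches with
multiple feasible candidates are flagged ambiguous. Manually curated
identity columns should be used verbatim instead. (A purely greedy
mutual-nearest-neighbour rule was considered; optimal assignment was
chosen because it resolves the two-cell swap case correctly and is equally
deterministic.)

## Synthetic-data generators

The generators emulate the in-vitro calibration assays so that every
analysis path is testable without downloads; they are first-class, tested
code.

* **Retention assay**: depths {0.5, 1.5, 3.0} mm with 7/8/8 replicates
  plus a 4-replicate delivered-dose reference group (true fraction 1,
  excluded by fitters), β_true = 0.24 by default. Noise is additive
  Gaussian on the fraction scale (default σ = 0.05) with post-noise
  clamping to [0, 1]; the clamped-row count is recorded so fitters can
  detect boundary pile-up. A multiplicative lognormal option exists
  because photon-count signals are heavy-tailed; no noise model is
  canonical, so both are explicit.
* **Growth assay**: volumes {0.1, 0.25, 0.5, 1.0} µL with 8/7/4/4
  replicates, γ_true = 3, multiplicative lognormal noise (σ_log = 0.15).
  The default fold-change ceiling Gmax = 4.0 over the assay window is the
  package's stand-in for an unconstrained expansion of a fast neural
  stem-cell line; no published value exists for it.
* **Peri-graft scene**: 10 peri-graft and 8 distal static neurons over 6
  days; peri calcium multiplier (6, 10, 8, 3, 1, 1) — peaking days 1–2,
  at rest by day 4 — against a flat distal baseline, with additive
  Gaussian intensity noise over a constant imaging background. Microglia
  (n = 20) follow a recruitment profile (0.10, 0.30, 0.80, 0.55, 0.35,
  0.20): each day exactly `round(n·p_day)` cells are designated in-circle
  with persistence across days, so the recruitment time-course (peak day
  2) holds by construction; movement draws per-cell lognormal step scales
  (median 25 µm/day, cell-to-cell log-SD 0.4) and falls back to placement
  within the designated region when a drawn step cannot reach it. Zero
  motility freezes cells in place. The scene reproduces the *qualitative*
  dynamics of peri-graft imaging — it does not model photon physics,
  segmentation error, registration drift between sessions, or genuinely
  diffusive microglial search, so passing tests demonstrate that the
  analytics preserve injected contrast and counts, not that they would be
  unbiased on real imaging data.

## Numerical choices and degenerate inputs

Retention/growth evaluation uses `expm1`/`log1p` for accuracy near zero.
Near full saturation (β·d ≳ 20) R sits within one ulp of 1 and the
analytic inverse is recoverable only to ~1e−7; tests acknowledge this.
Negative depths, volumes, and distances raise domain errors; `r ≤ margin`
returns exactly 0 hypoperfusion; an all-identical-depth (or -volume)
design raises an ill-posed error before optimisation. Schedule volumes are
conserved exactly by assigning the division remainder to the deepest step.
Linker determinism comes from sorting points by (day, x, y, z) before
assignment.

## Problem sizes

Default simulation sizes keep the whole suite lightweight while leaving
the statistics meaningful: 200 replicates per rung of the noise ladder,
500 simulated assays × 1000 bootstrap resamples for the CI-coverage check,
and 10⁵ Monte-Carlo points per radius for the geometry oracle.

## Known limitations

* β and the 100-µm margin are calibration-specific; transferring them
  across tissues, species or cell preparations requires re-estimation.
* No reaction–diffusion or Krogh-cylinder oxygen model, no vascularisation
  dynamics, no backflow fluid mechanics, no cell-concentration crowding
  term, and no optimisation over injection schedules.
* The aggregate retention of a multi-step plan is an uncalibrated
  volume-weighted estimate; empirical pulse-elevation data were compared
  only qualitatively to single-bolus predictions.
* Estimation is frequentist OLS with percentile bootstrap; no
  measurement-error-in-depth, mixed-effects or Bayesian variants.
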
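# graftkit

Quantitative planning and analysis tools for intracerebral cell
transplantation. Written for experimentalists who deliver cell suspensions
into brain tissue (or gel phantoms) through fine glass pipettes and want
model-based answers to the two protocol questions that dominate early graft
outcome: **how deep to inject** (cells reflux up the needle track at shallow
depths) and **how much to inject** (large boluses develop a hypoxic core).

## The models

**Retention vs depth.** Tissue viscosity seals the needle track with a force
that grows with insertion depth *d* (mm), `N(d) = k·dⁿ`. Folding the sealing
scale and the sensitivity of retention to sealing into one rate β gives a
one-parameter saturating law for the retained fraction:

```
R(d) = 1 − e^(−β·d)
```

R(0) = 0 (everything refluxes at the surface) and R → 1 asymptotically; β
(1/mm) is re-estimated per tissue/cell/needle configuration from a
calibration assay. A published calibration in soft agarose gives β ≈ 0.24/mm.

**Hypoperfusion vs volume.** An implanted cell mass is avascular for days;
treating it as a sphere whose outer shell within a margin (default 100 µm,
motivated by the mono-exponential oxygen decay pO₂(L) = pO₂cap·e^(−L/λ) with
λ = 30 µm) stays oxygenated, the hypoperfused fraction is

```
HypoR(r) = ((r − margin)/r)³,   r > margin   (else 0)
```

with `v = (4/3)πr³` linking radius to injected volume. The onset threshold
V_th = (4/3)π·margin³ ≈ 4.2 nL; a 100-nL bolus predicts HypoR = 0.278. Early
graft growth follows `G(v) = Gmax·(1 − HypoR(v))^γ` with γ = 3 by default.

Around the models the package provides bounded nonlinear least-squares
estimation with 1000× site-resampled bootstrap CIs, goodness-of-fit and
Spearman residual-trend diagnostics, exponent (γ) model selection, ±20%
sensitivity sweeps, inverse planners (depth for a target retention, maximal
volume for a hypoperfusion budget, pulse-elevation injection schedules),
peri-graft two-photon analytics (120-µm proximity classification, microglia
recruitment counts, calcium-trace normalisation, 3D migration metrics), and
seeded synthetic-data generators mirroring the calibration experiments.

## Worked example

Predict the consequences of a 100-nL bolus at 0.5 mm:

```
$ graftkit predict --volume-nl 100 --depth-mm 0.5
{
  "v_th_nl": 4.1887902047863905,
  "radius_um": 287.9411911484861,
  "volume_nl": 100.0,
  "hypor": 0.2780702545277185,
  "depth_mm": 0.5,
  "retention": 0.11307956328284248
}
```

A 100-nL deposit forms a ~288-µm-radius sphere, so 27.8% of the cells sit
more than 100 µm from perfused host tissue, and a single 0.5-mm bolus is
predicted to retain only ~11% of the dose. The pulse-elevation planner
splits the dose into five 20-nL steps at 0.5/0.4/0.3/0.2/0.1 mm with 20-s
pauses (`graftkit plan --total-nl 100`) and reports per-step retention
{0.113, 0.092, 0.069, 0.047, 0.024}, a volume-weighted aggregate of 0.069,
and HypoR = 0.278 for the pooled deposit.

The same models run from Python:

```python
import graftkit as gk

df = gk.simulate_retention(gk.RetentionSimSpec(beta_true=0.24, seed=1))
fit = gk.fit_retention(df, gk.FitConfig(n_boot=1000, seed=2))
fit.estimates["beta"], fit.ci["beta"]   # ~0.24 with a bootstrap 95% CI
```

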
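# Methods

## Dose model

Absorbed dose is computed per VOI (lesion or organ) under the local energy
deposition approximation: every decay inside the VOI deposits its mean
electron/beta energy locally and photon dose is neglected. The energy per
decay defaults to E = 2.3694·10⁻¹⁴ J (≈147.9 keV, the mean locally deposited
electron energy per ¹⁷⁷Lu decay from standard decay-data compilations); it is
a configuration value, never hard-coded in operations. Density defaults to
1.0 g/mL and is taken from the input table; mass = volume × density.

Activity is counts/(duration × CF), with CF the system sensitivity in
counts/s/MBq from a calibration measurement. The dose rate is therefore
linear in counts and inverse-linear in VOI mass, which the engine's
property tests exploit.

**Time integration.** Fully sampled cycles (4/24/72/192 h) are fitted with a
monoexponential by unweighted least squares on log dose rate. This choice is
closed-form, robust with 3–4 points, and exact on noise-free data; a
nonlinear refinement on the linear scale is available behind
`EngineConfig(refine_fit=True)` but changes results only under strong noise.
The integral runs from injection time (t = 0) to infinity, AD = Ḋ₀/λ, i.e.
the fitted curve is back-extrapolated to injection. Fits with
λ_eff below the ¹⁷⁷Lu physical decay constant (ln 2 / 159.53 h) are
physically impossible but reachable under noise; they are flagged in the run
warnings, and rejected only in strict mode.

**Single-time-point cycles.** Later cycles acquired only at 24 h are scaled
from the reference cycle (the last fully sampled one, cycle 2 by default) by
the ratio of 24 h counts times the inverse ratio of VOI volumes. When the
washout rate truly carries over from the reference cycle this is exact; the
noise-free end-to-end test verifies agreement with the multi-time-point
answer to better than 10⁻⁶ relative.

**Partial-volume correction.** Lesion ADs are divided by a recovery
coefficient RC(V) before summation into CumAD; healthy organs are treated as
large and left uncorrected. The default curve is piecewise-linear through
sphere-phantom knots with RC(2 mL) = 0.5, clamped outside the knot range.
Curves fitted from phantom measurements go through isotonic regression
(pool-adjacent-violators) so they are monotone even under measurement noise.
Dividing AD by RC is equivalent to scaling counts under the engine's
linearity, which is why the correction sits at the AD level.

**Volume convention.** By default each structure's first-cycle (baseline)
volume is used for mass and RC at every cycle (constant-volume dosimetry,
the convention of clinical practice when lesions cannot be re-delineated on
low-dose CT); `volume_mode="per_cycle"` switches to the per-cycle volumes.

## Lesion selection and response

Bone lesions are excluded (response cannot be assessed reliably), lesions
under 2 cm³ are excluded (RC ≈ 0.5 and below; partial-volume effect
dominates), and at most 5 lesions per patient and site are kept. The cap
always retains the site's largest and smallest lesion; remaining slots fill
by descending volume with ties broken by lesion id — only the max/min
inclusion is a hard rule, the fill order is this package's deterministic
choice. The 2 cm³ floor applies at baseline only. Lesions lacking a
follow-up volume keep a `missing_followup` flag: they stay in the dose
indices but are excluded from dose-response fitting.

ΔV% = 100·(V_M3 − V_BL)/V_BL. "Controlled" is ΔV% ≤ 0; "stable" is
ΔV% ≤ +20 (a strict increase above 20 % breaks stability); both boundaries
inclusive, so controlled ⇒ stable.

## Statistics

**Dose–response.** ΔV% vs total AD is modelled as
floor + (cap − floor)·e^(−rate·AD). For a fixed rate the model is linear in
(floor, cap), so fitting profiles the rate over a log-spaced grid with a
bounded golden-section refinement — fast enough for dense bootstrapping and
immune to bad starting values. Uncertainty comes from a patient-level
cluster bootstrap (default 1000 resamples, percentile 95 % CIs), respecting
within-patient correlation of lesions. The monotone association is
summarised by Spearman's ρ and its p value. A `fixed_rate=0` mode collapses
the model to the constant mean for nested-model checks. A linear-in-dose
sensitivity alternative is the `fixed_rate` path with a free linear fit via
the same profile machinery.

**TCP.** Binary logistic regression (maximum likelihood via statsmodels) of
the controlled flag on total AD. Separation — a single outcome class,
non-convergence, or runaway coefficients — triggers a Firth-penalised
(Jeffreys prior) Newton refit, implemented here because no installed package
provides it; the model is flagged accordingly. Doses at 50 % and 90 %
control probability are reported when the slope is positive.

**Toxicity.** Spearman ρ between organ CumAD and percent lab change, with an
exact permutation p for n ≤ 9 (full enumeration) and the large-sample
approximation otherwise; LOWESS trends are exported for plotting.
Baseline-vs-follow-up labs use paired two-sided t tests; all-zero
differences give p = 1 by continuity, zero-variance nonzero differences are
an error.

**Survival.** Patients are dichotomized at the cohort median of a dose
index, values equal to the median going to the high group. Kaplan–Meier
curves with Greenwood CIs, group medians with not-reached handling, a Cox
proportional-hazards HR (high vs low, Efron tie handling — lifelines'
default) with Wald CI and p, and a log-rank test. A group without events
leaves the HR flagged non-estimable while KM curves are still returned. No
multiple-testing adjustment is applied across analyses.

## Synthetic cohort: what it emulates

Defaults describe one fixed study condition: 35 patients, 1–9 lesions each
(~150 analysable lesions), lesion sites ≈ 59 % liver / 22 % nodes / small
fractions mesentery, pancreas, peritoneum plus 10 % bone so the exclusion
rule is exercised; lesion volumes lognormal (median 10 mL, σ_log = 1);
number of cycles 2/3/4 with weights 0.06/0.08/0.86. Kinetics per structure
class: initial activity concentration lognormal (lesions: median
3.4 MBq/mL, σ_log = 0.7) and effective half-life truncated-normal bounded
above by the physical half-life (lesions: mean 80 h). These land the
per-cycle lesion dose medians near 32/26/22/18 Gy across cycles 1–4 and the
total near 95 Gy, with organ doses at clinically typical levels (kidneys
≈ 2.7 Gy/cycle, marrow ≈ 0.3 Gy/cycle). Uptake declines by a factor 0.84
per cycle (matching the observed cycle-1→4 decline); washout rate is
constant across cycles within a structure, which is what makes
single-time-point scaling exact in the noise-free limit.

Counts are Poisson with mean A₀·V·e^(−λt)·CF·duration·RC(V)
(CF = 10 counts/s/MBq, 2700 s acquisitions — ≥10⁴ counts for essentially all
lesion VOIs at 24 h). The response layer draws
ΔV% from the plateaued curve (floor −40 %, cap +30 %, rate 0.015/Gy,
noise SD 10 %), which reproduces ≈ −22 % shrinkage near 93 Gy and universal
stability above ~95 Gy. Lab changes decline linearly in marrow CumAD
(platelets 37 %/Gy, lymphocytes 30 %/Gy, leukocytes 24 %/Gy, neutrophils
23 %/Gy, hemoglobin 8 %/Gy, GFR 0 — magnitudes consistent with a
0.3→0.9 Gy marrow CumAD increase driving 15–22 % declines) with 8 % noise.
Survival is exponential with log-hazard −0.013/Gy in the mean total lesion
AD, anchored at median PFS 30 months / OS 57 months for a 90 Gy patient,
with uniform 36–72 month administrative censoring (~60 % PFS events).

What it does **not** emulate: reconstruction artefacts and spatially
correlated noise, registration and segmentation error, intra-patient
kinetic correlation beyond an optional shared log-uptake random effect
(default off — no cohort value exists to match), volume change over cycles,
non-monoexponential washout, and informative censoring. Passing tests
therefore demonstrate correctness of the computational chain under the
stated statistical model, not clinical performance on real images.

A sphere phantom (`generate_phantom_images`) provides the RC calibration
path: uniform spheres on a 3-D grid blurred with an isotropic Gaussian PSF,
RC measured as the in-mask fraction. Its surface-loss behaviour follows the
expected ≈ 3σ/(√(2π)·R) scaling; very large spheres require their own grid.

## Numerical and design notes

- All randomness flows from `numpy.random.default_rng(seed)`; a fixed seed
  reproduces every table byte for byte, and the pipeline manifest checks
  this through file checksums. Output CSVs are read back with round-trip
  float parsing so tables re-serialize identically.
- Closed-form integration is cross-checked against adaptive quadrature plus
  an analytic tail (relative 10⁻⁶) in a property sweep.
- Monte Carlo checks in the test suite use medians over seeded replicates
  where a single draw's sampling error would be comparable to the tolerance
  (logistic slope, Cox log-HR); simulation sizes (200 coverage replicates ×
  1000 bootstrap resamples; 1000 null replicates for the log-rank size
  check; 35-patient cohorts throughout) were chosen as the smallest designs
  whose Monte Carlo error is well below the quantities being checked.
- Whether the clinical software fitted activity or dose rate before
  conversion is immaterial under LED linearity; this engine fits dose rate.
- Degenerate inputs are first-class: zero counts are valid (zero dose),
  all-controlled TCP data triggers the penalised path, groups without
  events keep their KM curves, and patients with no selected lesions are
  dropped from dose indices with a warning.

## Known limitations

- LED ignores photon cross-dose; organ doses (especially marrow) are
  underestimates relative to full transport. The engine is deliberately
  VOI-local.
- The STP scaling inherits the reference cycle's washout rate; if kinetics
  change between cycles the later-cycle ADs are biased accordingly.
- Percentile bootstrap CIs undercover slightly for strongly skewed
  parameters at small patient counts.
- The survival layer assumes proportional hazards with exponential
  baseline; the Cox recovery tests validate estimation under that model
  only.
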
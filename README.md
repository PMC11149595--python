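# lutadose

VOI-based internal dosimetry and dose–outcome analysis for
[¹⁷⁷Lu]Lu-DOTATATE peptide receptor radionuclide therapy (PRRT) of
gastroenteropancreatic neuroendocrine tumors, plus a synthetic-cohort
generator with known ground truth for validating every stage.

Patients on a fixed PRRT regimen (7.4 GBq every 8 weeks, up to 4 cycles)
receive widely varying absorbed doses (AD, Gy) in tumors and organs at risk.
`lutadose` turns per-VOI SPECT count measurements into per-cycle and
cumulative absorbed doses, and relates them to tumor volume response,
hematologic toxicity and survival. It is aimed at medical-physics and
nuclear-medicine groups prototyping dosimetry-driven analyses on tabular VOI
data.

## Method

**Dose engine.** Counts in a VOI are converted to activity through a system
calibration factor (counts/s/MBq), then to an absorbed-dose rate under the
local energy deposition (LED) approximation with density correction:

    Ḋ = A·E·3600 / m      (Gy/h, A in Bq, E ≈ 2.3694·10⁻¹⁴ J per ¹⁷⁷Lu decay,
                           m the VOI mass in kg; photons neglected)

For fully sampled cycles (acquisitions at 4, 24, 72 and 192 h
post-injection) the dose-rate curve is fitted with a monoexponential
Ḋ(t) = Ḋ₀·e^(−λt) (log-linear least squares) and integrated in closed form,
AD = Ḋ₀/λ. For simplified later cycles with a single 24 h acquisition,

    AD_new = AD_ref · (counts₂₄,new / counts₂₄,ref) · (V₂₄,ref / V₂₄,new)

scaled off the last fully sampled (reference) cycle. Lesion doses are
divided by a volume-dependent recovery coefficient (RC; piecewise-linear,
RC = 0.5 at 2 mL by default) to correct partial-volume losses, then summed
over cycles into the cumulative dose CumAD.

**Response and selection.** Target lesions: bone sites and lesions under
2 cm³ excluded, at most 5 per organ/site (always including the site's
largest and smallest). Response is ΔV% = 100·(V_M3 − V_BL)/V_BL between
baseline CT and the CT 3 months after the last cycle; ΔV% ≤ 0 is
"controlled", ΔV% ≤ +20 "stable".

**Outcome statistics.** ΔV% vs total AD is fitted with a plateaued
exponential (floor + (cap − floor)·e^(−rate·AD)) with patient-cluster
bootstrap CIs; tumor control probability is a binary logistic regression of
the controlled flag on AD (Firth fallback under separation); organ CumAD vs
percent lab change uses Spearman rank correlation (exact permutation p for
n ≤ 9) and LOWESS trends; baseline-vs-follow-up labs use paired t tests;
survival (PFS/OS) is compared between patients above/below the cohort median
of a dose index (mean/min/max total lesion AD) with Kaplan–Meier curves, a
Cox hazard ratio (Efron ties) and a log-rank test.

**Synthetic cohort.** Because real SPECT cohorts are not publicly
deposited, `lutadose.synthetic_cohort` generates seeded 35-patient cohorts
with monoexponential washout, Poisson counting noise, volume-dependent
partial-volume loss, a plateaued dose–response, dose-dependent hematologic
decline and proportional-hazards survival — together with the exact truth
tables that produced them.

## Worked example

```bash
lutadose run --seed 7 --out demo/     # or: lutadose run --config examples/demo.yaml
```

runs simulate → dose → respond → analyze and writes CSV tables, a
`statistics.json` and a run manifest. With seed 7 the demo cohort gives
(from `demo/statistics.json`):

- dose–response: floor −40.2 %, cap +31.0 %, rate 0.015 /Gy over n = 151
  lesions, Spearman ρ = −0.85 — higher total AD, more shrinkage, with a
  plateau at high doses;
- TCP: slope +0.109 /Gy, dose at 50 % control probability ≈ 41 Gy;
- survival: PFS hazard ratio 0.38 (95 % CI 0.15–0.97, p = 0.04) for
  patients above vs below the median mean-total-AD — higher lesion doses,
  slower progression;
- toxicity: marrow CumAD vs platelet change ρ = −0.81 (p < 10⁻⁸).

The same API is available in Python (`lutadose.generate_cohort`,
`lutadose.process_cohort`, `lutadose.fit_dose_response`, ...); every stage
also accepts external CSVs matching the schemas in
`lutadose.pipeline.SCHEMAS`.

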
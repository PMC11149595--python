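"""Seeded synthetic PRRT cohorts with known ground truth.

Emulates a 35-patient, ~150-lesion [177Lu]Lu-DOTATATE dosimetry cohort:
monoexponential washout of activity per structure, Poisson counting noise,
volume-dependent partial-volume loss, a plateaued dose-volume response,
dose-dependent hematologic decline and a proportional-hazards survival
layer.  Every generated observation is paired with the truth that produced
it, so each downstream stage can be checked against a known answer.

All randomness flows from one root ``numpy`` generator seeded in the config;
a fixed seed reproduces the tables byte for byte.  A noise-free mode
replaces every stochastic draw in the measurement model with its mean for
exact-arithmetic tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .dose_engine import (
    DEFAULT_LED_CONSTANT_J,
    LU177_LAMBDA_PHYS,
    LU177_PHYSICAL_HALF_LIFE_H,
    MBQ_TO_BQ,
    RecoveryCurve,
    SECONDS_PER_HOUR,
)

HEALTHY_ORGANS = ("liver", "kidneys", "spleen", "bone_marrow")
LESION_SITES = ("liver", "lymph_node", "mesentery", "pancreas", "peritoneum", "bone")
LAB_NAMES = ("hemoglobin", "leukocytes", "lymphocytes", "neutrophils", "platelets", "gfr")

#: Acquisition schedule (hours post-injection) for fully sampled cycles.
FULL_SCHEDULE_H = (4.0, 24.0, 72.0, 192.0)
#: Single-time-point schedule for the simplified later cycles.
STP_SCHEDULE_H = (24.0,)


class CohortConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class KineticsPrior:
    """Per structure class: initial activity concentration and effective half-life.

    a0 is lognormal (median MBq/mL, log-sigma); the effective half-life is a
    normal truncated to (thalf_lo, physical half-life of 177Lu) so biological
    clearance is never negative.
    """

    a0_median_mbq_ml: float
    a0_log_sigma: float
    thalf_mean_h: float
    thalf_sd_h: float
    thalf_lo_h: float = 12.0


def _default_kinetics() -> dict:
    # Medians tuned so noise-free organ/lesion doses land in the clinically
    # typical ranges (lesions tens of Gy per cycle, kidneys ~3 Gy, marrow <1 Gy).
    return {
        "lesion": KineticsPrior(3.4, 0.7, 80.0, 20.0),
        "liver": KineticsPrior(0.15, 0.35, 60.0, 10.0),
        "kidneys": KineticsPrior(0.44, 0.35, 50.0, 10.0),
        "spleen": KineticsPrior(0.43, 0.35, 65.0, 10.0),
        "bone_marrow": KineticsPrior(0.06, 0.35, 40.0, 8.0),
    }


def _default_sites() -> dict:
    # Analysed-lesion mix (~65% liver, 25% nodes) plus a bone fraction so the
    # bone-exclusion rule is exercised.
    return {
        "liver": 0.59,
        "lymph_node": 0.22,
        "mesentery": 0.04,
        "pancreas": 0.03,
        "peritoneum": 0.02,
        "bone": 0.10,
    }


def _default_organ_volumes() -> dict:
    # (mean mL, sd mL); bone marrow is the trabecular L2-L4 surrogate VOI.
    return {
        "liver": (1500.0, 250.0),
        "kidneys": (300.0, 50.0),
        "spleen": (200.0, 60.0),
        "bone_marrow": (45.0, 8.0),
    }


@dataclass(frozen=True)
class ResponseModel:
    """Plateaued dose-volume response: dV% = floor + (cap-floor)*exp(-rate*AD) + noise."""

    floor: float = -40.0
    cap: float = 30.0
    rate_per_gy: float = 0.015
    noise_sd: float = 10.0


@dataclass(frozen=True)
class ToxicityModel:
    """Percent lab change at month 3 is linear in bone-marrow CumAD plus noise.

    Slopes are % decline per Gy of marrow CumAD; baselines are (mean, sd) of
    the pre-treatment lab values.
    """

    slopes_pct_per_gy: dict = field(
        default_factory=lambda: {
            "hemoglobin": 8.0,
            "leukocytes": 24.0,
            "lymphocytes": 30.0,
            "neutrophils": 23.0,
            "platelets": 37.0,
            "gfr": 0.0,
        }
    )
    noise_sd_pct: float = 8.0
    baselines: dict = field(
        default_factory=lambda: {
            "hemoglobin": (13.4, 1.3),
            "leukocytes": (6.5, 2.2),
            "lymphocytes": (1.5, 0.5),
            "neutrophils": (4.0, 1.3),
            "platelets": (218.0, 68.0),
            "gfr": (72.1, 15.0),
        }
    )


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential survival with log-hazard linear in mean total lesion AD.

    Hazards are per month, parameterised at a reference dose so the baseline
    corresponds to a mid-cohort patient; censoring is administrative at a
    uniform follow-up horizon.
    """

    log_hazard_per_gy: float = -0.013
    reference_dose_gy: float = 90.0
    pfs_hazard_at_ref: float = math.log(2.0) / 30.0
    os_hazard_at_ref: float = math.log(2.0) / 57.0
    followup_range_months: tuple = (36.0, 72.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort; defaults are the generated cohort."""

    n_patients: int = 35
    lesions_per_patient_range: tuple = (1, 9)
    site_distribution: dict = field(default_factory=_default_sites)
    volume_lognormal_params: tuple = (math.log(10.0), 1.0)  # (mu, sigma) of mL
    min_lesion_volume_ml: float = 0.5
    kinetics_priors: dict = field(default_factory=_default_kinetics)
    organ_volumes: dict = field(default_factory=_default_organ_volumes)
    injected_activity_mbq: float = 7400.0
    n_cycles_distribution: dict = field(default_factory=lambda: {2: 0.06, 3: 0.08, 4: 0.86})
    cycle_dose_decay: float = 0.84
    response: ResponseModel = field(default_factory=ResponseModel)
    toxicity: ToxicityModel = field(default_factory=ToxicityModel)
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    calibration_cps_per_mbq: float = 10.0
    acquisition_duration_s: float = 2700.0
    rc_curve: RecoveryCurve = field(default_factory=RecoveryCurve.default)
    led_constant_j: float = DEFAULT_LED_CONSTANT_J
    density_g_ml: float = 1.0
    patient_kinetic_effect_sd: float = 0.0  # optional shared log-A0 random effect
    noise_free: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, weights in (
            ("site_distribution", self.site_distribution),
            ("n_cycles_distribution", self.n_cycles_distribution),
        ):
            w = np.array(list(weights.values()), dtype=float)
            if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
                raise CohortConfigError(f"{name} weights must be >= 0 and sum to 1")
        if self.n_patients < 1:
            raise CohortConfigError("n_patients must be >= 1")
        lo, hi = self.lesions_per_patient_range
        if not (1 <= lo <= hi):
            raise CohortConfigError("lesions_per_patient_range must satisfy 1 <= lo <= hi")
        if self.volume_lognormal_params[1] <= 0:
            raise CohortConfigError("lesion volume log-sigma must be > 0")
        if not (0 < self.cycle_dose_decay <= 1.5):
            raise CohortConfigError("cycle_dose_decay must be positive")
        for cls, prior in self.kinetics_priors.items():
            if prior.thalf_mean_h <= 0 or prior.thalf_mean_h > LU177_PHYSICAL_HALF_LIFE_H:
                raise CohortConfigError(
                    f"{cls}: half-life prior mean must lie in (0, physical half-life]"
                )
            if prior.thalf_sd_h < 0 or prior.a0_log_sigma < 0:
                raise CohortConfigError(f"{cls}: variance parameters must be >= 0")
        if self.response.noise_sd < 0 or self.toxicity.noise_sd_pct < 0:
            raise CohortConfigError("noise SDs must be >= 0")


@dataclass
class CohortTables:
    """Generated observations plus the truth that produced them.

    The truth tables are for verification only; the analysis pipeline never
    reads them.
    """

    timepoints: pd.DataFrame
    lesions: pd.DataFrame
    labs: pd.DataFrame
    survival: pd.DataFrame
    truth_kinetics: pd.DataFrame
    truth_lesions: pd.DataFrame
    truth_patients: pd.DataFrame

    def to_dir(self, out_dir) -> dict:
        """Write all tables as CSV; returns name -> path."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in (
            "timepoints", "lesions", "labs", "survival",
            "truth_kinetics", "truth_lesions", "truth_patients",
        ):
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths


def draw_half_life(rng: np.random.Generator, prior: KineticsPrior, size=None):
    """Effective half-life draws (h), truncated to (thalf_lo, physical half-life)."""
    a = (prior.thalf_lo_h - prior.thalf_mean_h) / prior.thalf_sd_h
    b = (LU177_PHYSICAL_HALF_LIFE_H - prior.thalf_mean_h) / prior.thalf_sd_h
    return stats.truncnorm.rvs(
        a, b, loc=prior.thalf_mean_h, scale=prior.thalf_sd_h, size=size, random_state=rng
    )


def doserate_at_injection(a0_conc_mbq_ml: float, density_g_ml: float, led_constant_j: float) -> float:
    """Gy/h at t=0 for a uniform concentration under local energy deposition."""
    mass_per_ml_kg = density_g_ml / 1000.0
    return a0_conc_mbq_ml * MBQ_TO_BQ * led_constant_j * SECONDS_PER_HOUR / mass_per_ml_kg


def true_absorbed_dose(a0_conc_mbq_ml, lambda_eff, density_g_ml, led_constant_j) -> float:
    """Closed-form AD (Gy): integral of the generating dose-rate curve to infinity."""
    return doserate_at_injection(a0_conc_mbq_ml, density_g_ml, led_constant_j) / lambda_eff


def _expected_counts(a0_conc, volume_ml, lam, t_h, cfg: CohortConfig, rc: float) -> float:
    return (
        a0_conc
        * volume_ml
        * math.exp(-lam * t_h)
        * cfg.calibration_cps_per_mbq
        * cfg.acquisition_duration_s
        * rc
    )


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> CohortTables:
    """Generate one synthetic cohort; ``seed`` overrides the config seed."""
    cfg = config or CohortConfig()
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    rng = np.random.default_rng(cfg.seed)

    site_names = list(cfg.site_distribution)
    site_w = np.array([cfg.site_distribution[s] for s in site_names], dtype=float)
    cyc_vals = np.array(sorted(cfg.n_cycles_distribution), dtype=int)
    cyc_w = np.array([cfg.n_cycles_distribution[int(c)] for c in cyc_vals], dtype=float)
    lo, hi = cfg.lesions_per_patient_range

    tp_rows, lesion_rows, truth_kin, truth_les, truth_pat = [], [], [], [], []
    lab_rows, surv_rows = [], []

    for ip in range(cfg.n_patients):
        pid = f"P{ip + 1:03d}"
        n_cycles = int(rng.choice(cyc_vals, p=cyc_w / cyc_w.sum()))
        pat_effect = (
            rng.normal(0.0, cfg.patient_kinetic_effect_sd)
            if cfg.patient_kinetic_effect_sd > 0
            else 0.0
        )

        structures = []  # (structure_id, class, volume, a0_conc, lambda)
        for organ in HEALTHY_ORGANS:
            mu, sd = cfg.organ_volumes[organ]
            vol = max(float(rng.normal(mu, sd)), 5.0)
            prior = cfg.kinetics_priors[organ]
            a0 = float(
                np.exp(np.log(prior.a0_median_mbq_ml) + prior.a0_log_sigma * rng.standard_normal())
            )
            lam = math.log(2.0) / float(draw_half_life(rng, prior))
            structures.append((organ, organ, vol, a0, lam))

        n_lesions = int(rng.integers(lo, hi + 1))
        prior = cfg.kinetics_priors["lesion"]
        for il in range(n_lesions):
            lid = f"{pid}-L{il + 1:02d}"
            site = site_names[int(rng.choice(len(site_names), p=site_w / site_w.sum()))]
            mu, sigma = cfg.volume_lognormal_params
            vol = max(float(rng.lognormal(mu, sigma)), cfg.min_lesion_volume_ml)
            a0 = float(
                np.exp(
                    np.log(prior.a0_median_mbq_ml)
                    + pat_effect
                    + prior.a0_log_sigma * rng.standard_normal()
                )
            )
            lam = math.log(2.0) / float(draw_half_life(rng, prior))
            structures.append((lid, "lesion", vol, a0, lam))
            lesion_rows.append(
                {"patient_id": pid, "lesion_id": lid, "site": site, "v_bl_ml": vol}
            )

        # --- time-activity observations and kinetic truth ---
        lesion_total_ad: dict = {}
        organ_cum_ad: dict = {}
        for sid, sclass, vol, a0_1, lam in structures:
            rc = float(cfg.rc_curve(vol)) if sclass == "lesion" else 1.0
            for cyc in range(1, n_cycles + 1):
                a0_c = a0_1 * cfg.cycle_dose_decay ** (cyc - 1)
                ad_true = true_absorbed_dose(a0_c, lam, cfg.density_g_ml, cfg.led_constant_j)
                truth_kin.append(
                    {
                        "patient_id": pid,
                        "cycle": cyc,
                        "structure_id": sid,
                        "structure_class": sclass,
                        "a0_mbq_ml": a0_c,
                        "lambda_eff_per_h": lam,
                        "ad_gy": ad_true,
                    }
                )
                if sclass == "lesion":
                    lesion_total_ad[sid] = lesion_total_ad.get(sid, 0.0) + ad_true
                else:
                    organ_cum_ad[sid] = organ_cum_ad.get(sid, 0.0) + ad_true
                schedule = FULL_SCHEDULE_H if cyc <= 2 else STP_SCHEDULE_H
                for t in schedule:
                    mean_counts = _expected_counts(a0_c, vol, lam, t, cfg, rc)
                    counts = (
                        mean_counts if cfg.noise_free else float(rng.poisson(mean_counts))
                    )
                    tp_rows.append(
                        {
                            "patient_id": pid,
                            "cycle": cyc,
                            "structure_id": sid,
                            "structure_class": sclass,
                            "t_h": t,
                            "counts": counts,
                            "duration_s": cfg.acquisition_duration_s,
                            "volume_ml": vol,
                            "density_g_ml": cfg.density_g_ml,
                        }
                    )

        # --- lesion volume response ---
        rm = cfg.response
        eligible_ads = []
        for row in lesion_rows[-n_lesions:]:
            total_ad = lesion_total_ad[row["lesion_id"]]
            mean_dv = rm.floor + (rm.cap - rm.floor) * math.exp(-rm.rate_per_gy * total_ad)
            dv = mean_dv if cfg.noise_free else mean_dv + float(rng.normal(0.0, rm.noise_sd))
            dv = max(dv, -98.0)
            if row["site"] == "bone":
                row["v_m3_ml"] = np.nan  # response not assessable at bone sites
            else:
                row["v_m3_ml"] = row["v_bl_ml"] * (1.0 + dv / 100.0)
            truth_les.append(
                {
                    "patient_id": pid,
                    "lesion_id": row["lesion_id"],
                    "site": row["site"],
                    "total_ad_gy": total_ad,
                    "delta_v_pct": dv,
                }
            )
            if row["site"] != "bone" and row["v_bl_ml"] >= 2.0:
                eligible_ads.append(total_ad)

        # --- toxicity labs driven by marrow CumAD ---
        marrow_cum = organ_cum_ad["bone_marrow"]
        tm = cfg.toxicity
        for lab in LAB_NAMES:
            b_mu, b_sd = tm.baselines[lab]
            baseline = max(float(rng.normal(b_mu, b_sd)), 0.05 * b_mu)
            mean_pct = -tm.slopes_pct_per_gy[lab] * marrow_cum
            pct = mean_pct if cfg.noise_free else mean_pct + float(rng.normal(0.0, tm.noise_sd_pct))
            pct = max(pct, -95.0)
            lab_rows.append(
                {
                    "patient_id": pid,
                    "lab": lab,
                    "baseline_value": baseline,
                    "month3_value": baseline * (1.0 + pct / 100.0),
                    "pct_change": pct,
                }
            )

        # --- survival from the proportional-hazards truth ---
        sm = cfg.survival
        mean_ad = float(np.mean(eligible_ads)) if eligible_ads else float(
            np.mean(list(lesion_total_ad.values()))
        )
        log_rel = sm.log_hazard_per_gy * (mean_ad - sm.reference_dose_gy)
        h_pfs = sm.pfs_hazard_at_ref * math.exp(log_rel)
        h_os = sm.os_hazard_at_ref * math.exp(log_rel)
        t_pfs = float(rng.exponential(1.0 / h_pfs))
        t_os = float(rng.exponential(1.0 / h_os))
        censor = float(rng.uniform(*sm.followup_range_months))
        surv_rows.append(
            {
                "patient_id": pid,
                "pfs_months": min(t_pfs, censor),
                "pfs_event": int(t_pfs <= censor),
                "os_months": min(t_os, censor),
                "os_event": int(t_os <= censor),
            }
        )
        truth_pat.append(
            {
                "patient_id": pid,
                "n_cycles": n_cycles,
                "mean_total_ad_gy": mean_ad,
                "marrow_cum_ad_gy": marrow_cum,
                "log_hazard_pfs": math.log(h_pfs),
                "log_hazard_os": math.log(h_os),
            }
        )

    return CohortTables(
        timepoints=pd.DataFrame(tp_rows),
        lesions=pd.DataFrame(
            lesion_rows, columns=["patient_id", "lesion_id", "site", "v_bl_ml", "v_m3_ml"]
        ),
        labs=pd.DataFrame(lab_rows),
        survival=pd.DataFrame(surv_rows),
        truth_kinetics=pd.DataFrame(truth_kin),
        truth_lesions=pd.DataFrame(truth_les),
        truth_patients=pd.DataFrame(truth_pat),
    )


# --- sphere phantom for recovery-coefficient calibration --------------------

class PhantomError(ValueError):
    """Invalid phantom geometry."""


def generate_phantom_images(
    sphere_volumes_ml,
    psf_sigma_mm: float,
    grid_shape=(64, 64, 64),
    voxel_mm: float = 2.0,
    activity_conc: float = 1.0,
):
    """Uniform spheres blurred by an isotropic Gaussian PSF.

    Spheres are placed on a diagonal lattice with clearance checks; the
    returned recovery coefficient per sphere is the in-mask fraction of the
    blurred activity relative to the ideal.  Returns
    ``(labels, ideal, blurred, rc_list)``.
    """
    if psf_sigma_mm < 0:
        raise PhantomError("psf_sigma must be >= 0")
    vols = np.asarray(sphere_volumes_ml, dtype=float)
    if np.any(vols <= 0):
        raise PhantomError("sphere volumes must be > 0")
    radii_mm = (3.0 * vols * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)

    shape = tuple(int(s) for s in grid_shape)
    extent = np.array(shape, dtype=float) * voxel_mm
    n = len(vols)
    # centres spread along the main diagonal, margins of one radius + 3 sigma
    fracs = np.linspace(0.18, 0.82, n) if n > 1 else np.array([0.5])
    centers = [fracs[i] * extent for i in range(n)]
    margin = 3.0 * psf_sigma_mm
    for i in range(n):
        lo = centers[i] - radii_mm[i]
        hi_ = centers[i] + radii_mm[i]
        if np.any(lo < 0) or np.any(hi_ > extent):
            raise PhantomError(f"sphere {i} (r={radii_mm[i]:.1f} mm) does not fit in the grid")
        for j in range(i + 1, n):
            dist = float(np.linalg.norm(centers[i] - centers[j]))
            if dist < radii_mm[i] + radii_mm[j] + max(margin, 1.0):
                raise PhantomError(f"spheres {i} and {j} overlap or nearly touch")

    coords = np.indices(shape, dtype=float)
    coords = (coords + 0.5) * voxel_mm  # voxel centres in mm
    labels = np.zeros(shape, dtype=np.int16)
    ideal = np.zeros(shape, dtype=float)
    for i in range(n):
        d2 = sum((coords[k] - centers[i][k]) ** 2 for k in range(3))
        mask = d2 <= radii_mm[i] ** 2
        labels[mask] = i + 1
        ideal[mask] = activity_conc

    if psf_sigma_mm > 0:
        blurred = ndimage.gaussian_filter(ideal, sigma=psf_sigma_mm / voxel_mm, mode="constant")
    else:
        blurred = ideal.copy()

    rc = []
    for i in range(n):
        mask = labels == i + 1
        total = float(ideal[mask].sum())
        rc.append(float(blurred[mask].sum()) / total if total > 0 else float("nan"))
    return labels, ideal, blurred, rc
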
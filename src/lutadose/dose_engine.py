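"""VOI-level absorbed-dose computation for [177Lu]Lu-DOTATATE therapy.

Converts per-VOI SPECT counts into absorbed doses (Gy) using the local
energy deposition (LED) approximation: every electron emitted by a decay
inside the VOI deposits its energy locally; photons are neglected.  Cycles
with a full acquisition schedule are time-integrated with a monoexponential
fit; later cycles with a single 24 h acquisition are scaled from the cycle-2
reference by a counts ratio and an inverse volume ratio.  Partial-volume
losses are corrected by dividing lesion doses by a volume-dependent recovery
coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

# --- physical constants -----------------------------------------------------

#: Physical half-life of 177Lu, hours (6.647 days).
LU177_PHYSICAL_HALF_LIFE_H = 6.647 * 24.0
#: Physical decay constant of 177Lu, 1/h.
LU177_LAMBDA_PHYS = math.log(2.0) / LU177_PHYSICAL_HALF_LIFE_H
#: Mean locally deposited (electron/beta) energy per 177Lu decay, joules
#: (~147.9 keV).  Configurable everywhere; never hard-coded in operations.
DEFAULT_LED_CONSTANT_J = 2.3694e-14

MBQ_TO_BQ = 1.0e6
SECONDS_PER_HOUR = 3600.0
GRAMS_PER_KG = 1000.0


class DoseEngineError(ValueError):
    """Base class for dosimetry input/precondition failures."""


class InsufficientDataError(DoseEngineError):
    """Fewer time points than the monoexponential fit requires."""


class NonClearingKineticsError(DoseEngineError):
    """Fitted effective decay constant is not positive."""


# --- calibration ------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationFactor:
    """System sensitivity: detected counts per second per MBq in the FOV."""

    cf: float
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.cf > 0:
            raise DoseEngineError(f"calibration factor must be > 0, got {self.cf}")


# --- recovery curve ---------------------------------------------------------

#: Default sphere-phantom recovery knots (volume mL, recovery coefficient).
#: Anchored at RC = 0.5 for a 2 mL sphere, the usual lesion-inclusion floor.
DEFAULT_RC_KNOTS = (
    (0.5, 0.20),
    (1.0, 0.35),
    (2.0, 0.50),
    (5.0, 0.72),
    (10.0, 0.85),
    (20.0, 0.92),
    (50.0, 0.97),
    (100.0, 0.99),
)


@dataclass(frozen=True)
class RecoveryCurve:
    """Piecewise-linear recovery coefficient vs VOI volume, clamped outside.

    Knots must have strictly increasing volumes and nondecreasing RC values
    in (0, 1].
    """

    volumes_ml: tuple[float, ...]
    rc: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes_ml, dtype=float)
        r = np.asarray(self.rc, dtype=float)
        if v.size != r.size or v.size < 1:
            raise DoseEngineError("recovery curve needs matching, non-empty knots")
        if v.size > 1 and not np.all(np.diff(v) > 0):
            raise DoseEngineError("recovery-curve volumes must be strictly increasing")
        if np.any(r <= 0) or np.any(r > 1):
            raise DoseEngineError("recovery coefficients must lie in (0, 1]")
        if v.size > 1 and np.any(np.diff(r) < 0):
            raise DoseEngineError("recovery coefficients must be nondecreasing in volume")

    @classmethod
    def default(cls) -> "RecoveryCurve":
        vols, rcs = zip(*DEFAULT_RC_KNOTS)
        return cls(vols, rcs)

    @classmethod
    def identity(cls) -> "RecoveryCurve":
        return cls((1.0,), (1.0,))

    def __call__(self, volume_ml):
        """RC at the given volume(s); linear between knots, clamped outside."""
        return np.interp(volume_ml, self.volumes_ml, self.rc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"volume_ml": self.volumes_ml, "rc": self.rc})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RecoveryCurve":
        df = df.sort_values("volume_ml")
        return cls(tuple(df["volume_ml"]), tuple(df["rc"]))


def fit_recovery_curve(volumes_ml, measured_fractions) -> RecoveryCurve:
    """Build a monotone recovery curve from sphere-phantom measurements.

    Non-monotone measured fractions are adjusted by isotonic regression
    (pool-adjacent-violators) before becoming knots; RC values are clipped
    to (0, 1].
    """
    v = np.asarray(volumes_ml, dtype=float)
    f = np.asarray(measured_fractions, dtype=float)
    if v.size < 2:
        raise DoseEngineError("at least 2 phantom spheres are required")
    if np.unique(v).size != v.size:
        raise DoseEngineError("phantom sphere volumes must be distinct")
    order = np.argsort(v)
    v, f = v[order], f[order]
    iso = IsotonicRegression(increasing=True)
    r = iso.fit_transform(v, f)
    r = np.clip(r, 1e-6, 1.0)
    return RecoveryCurve(tuple(v), tuple(r))


# --- count -> dose-rate conversion (LED) ------------------------------------

def counts_to_activity_mbq(counts: float, duration_s: float, cf: CalibrationFactor) -> float:
    """VOI activity in MBq from detected counts over an acquisition."""
    if duration_s <= 0:
        raise DoseEngineError("acquisition duration must be > 0")
    if counts < 0:
        raise DoseEngineError("counts must be >= 0")
    return counts / (duration_s * cf.cf)


def counts_to_doserate(
    counts: float,
    duration_s: float,
    volume_ml: float,
    density_g_ml: float,
    cf: CalibrationFactor,
    led_constant_j: float = DEFAULT_LED_CONSTANT_J,
) -> float:
    """Absorbed-dose rate (Gy/h) of a VOI under local energy deposition.

    activity A = counts / (duration * cf)            [MBq]
    mass      = volume * density                     [g]
    dose rate = A*1e6 [Bq] * E [J/decay] * 3600 [s/h] / (mass/1000 [kg])

    Linear in counts, inverse-linear in VOI mass.
    """
    if volume_ml <= 0 or density_g_ml <= 0:
        raise DoseEngineError("VOI volume and density must be > 0")
    a_mbq = counts_to_activity_mbq(counts, duration_s, cf)
    mass_kg = volume_ml * density_g_ml / GRAMS_PER_KG
    return a_mbq * MBQ_TO_BQ * led_constant_j * SECONDS_PER_HOUR / mass_kg


# --- monoexponential time-integration ---------------------------------------

@dataclass(frozen=True)
class MonoexpFit:
    """Fitted dose-rate curve d(t) = d0 * exp(-lambda_eff * t).

    ``below_physical`` flags fits whose effective decay constant falls below
    the 177Lu physical constant (impossible kinetics, but reachable under
    measurement noise).
    """

    d0: float                 # Gy/h at injection time
    lambda_eff: float         # 1/h
    residual_ss: float = 0.0  # SS of log-residuals
    n_points: int = 0
    below_physical: bool = False


def fit_monoexponential(
    t_h,
    doserate_gy_h,
    refine: bool = False,
    strict_physical_floor: bool = False,
) -> MonoexpFit:
    """Fit d(t) = d0*exp(-lambda*t) to >= 3 (time, dose-rate) points.

    The default objective is unweighted least squares on log dose rate
    (closed-form log-linear regression, well behaved with 3-4 points).
    ``refine=True`` polishes with nonlinear least squares on the linear
    scale.  Fits with lambda below the 177Lu physical decay constant are
    flagged, or rejected when ``strict_physical_floor`` is set.
    """
    t = np.asarray(t_h, dtype=float)
    d = np.asarray(doserate_gy_h, dtype=float)
    if t.size < 3:
        raise InsufficientDataError(
            f"monoexponential fit needs >= 3 time points, got {t.size}"
        )
    if np.unique(t).size != t.size:
        raise DoseEngineError("time points must be distinct")
    if np.any(d <= 0):
        raise DoseEngineError("dose rates must be strictly positive for the log fit")

    slope, intercept = np.polyfit(t, np.log(d), 1)
    lam = -slope
    d0 = math.exp(intercept)

    if refine:
        from scipy.optimize import curve_fit

        try:
            popt, _ = curve_fit(
                lambda tt, a, l: a * np.exp(-l * tt), t, d, p0=(d0, lam), maxfev=10000
            )
            d0, lam = float(popt[0]), float(popt[1])
        except RuntimeError:
            pass  # keep log-linear solution

    if lam <= 0:
        raise NonClearingKineticsError(
            f"fitted effective decay constant {lam:.4g}/h is not positive"
        )
    below = lam < LU177_LAMBDA_PHYS
    if below and strict_physical_floor:
        raise NonClearingKineticsError(
            f"lambda_eff {lam:.4g}/h below physical decay constant "
            f"{LU177_LAMBDA_PHYS:.4g}/h (strict mode)"
        )
    resid = np.log(d) - (math.log(d0) - lam * t)
    return MonoexpFit(
        d0=float(d0),
        lambda_eff=float(lam),
        residual_ss=float(resid @ resid),
        n_points=int(t.size),
        below_physical=bool(below),
    )


def integrate_monoexp(fit: MonoexpFit) -> float:
    """Absorbed dose (Gy): integral of d0*exp(-lambda*t) over [0, inf) = d0/lambda."""
    if fit.lambda_eff <= 0:
        raise NonClearingKineticsError("cannot integrate with lambda_eff <= 0")
    return fit.d0 / fit.lambda_eff


# --- single-time-point scaling ----------------------------------------------

def scale_single_timepoint(
    ad_cycle2_gy: float,
    counts24_new: float,
    counts24_c2: float,
    v24_c2_ml: float,
    v24_new_ml: float,
) -> float:
    """Later-cycle AD from one 24 h acquisition, scaled off the cycle-2 reference.

    AD_new = AD_c2 * (counts24_new / counts24_c2) * (V24_c2 / V24_new)
    """
    if counts24_c2 <= 0:
        raise DoseEngineError("reference 24 h counts must be > 0")
    if v24_c2_ml <= 0 or v24_new_ml <= 0:
        raise DoseEngineError("volumes must be > 0")
    if counts24_new < 0:
        raise DoseEngineError("counts must be >= 0")
    return ad_cycle2_gy * (counts24_new / counts24_c2) * (v24_c2_ml / v24_new_ml)


# --- partial-volume correction ----------------------------------------------

def apply_recovery_correction(ad_gy: float, volume_ml: float, curve: RecoveryCurve) -> float:
    """Divide an absorbed dose by the recovery coefficient at the VOI volume."""
    if volume_ml <= 0:
        raise DoseEngineError("volume must be > 0")
    rc = float(curve(volume_ml))
    if rc <= 0:
        raise DoseEngineError(f"recovery coefficient evaluated to {rc} <= 0")
    return ad_gy / rc


# --- per-course aggregation -------------------------------------------------

def compute_course_dosimetry(cycle_doses: pd.DataFrame) -> dict:
    """Per-structure cumulative doses and lesion dose indices for ONE patient.

    ``cycle_doses`` needs columns patient_id, cycle, structure_id,
    structure_class, ad_gy.  Returns ``cum_ad`` (structure -> CumAD) and the
    lesion indices (mean/min/max of lesion totals).
    """
    pids = cycle_doses["patient_id"].unique()
    if len(pids) != 1:
        raise DoseEngineError(f"expected a single patient, got {sorted(map(str, pids))}")
    cum = cycle_doses.groupby("structure_id", sort=True)["ad_gy"].sum()
    classes = cycle_doses.groupby("structure_id", sort=True)["structure_class"].first()
    lesion_totals = cum[classes == "lesion"]
    indices = {}
    if len(lesion_totals):
        indices = {
            "mean_total_ad": float(lesion_totals.mean()),
            "min_total_ad": float(lesion_totals.min()),
            "max_total_ad": float(lesion_totals.max()),
            "n_lesions": int(len(lesion_totals)),
        }
    return {"patient_id": pids[0], "cum_ad": cum, "indices": indices}


# --- cohort-level driver ----------------------------------------------------

@dataclass(frozen=True)
class EngineConfig:
    """Knobs of the dose computation.

    volume_mode: 'baseline' uses each structure's first-cycle volume for mass
    and RC at every cycle (constant-volume dosimetry); 'per_cycle' uses the
    volume recorded at that cycle.
    """

    led_constant_j: float = DEFAULT_LED_CONSTANT_J
    volume_mode: str = "baseline"
    refine_fit: bool = False
    strict_physical_floor: bool = False
    pve_classes: tuple[str, ...] = ("lesion",)
    min_timepoints_for_fit: int = 3
    reference_cycle: int = 2
    stp_time_h: float = 24.0

    def __post_init__(self) -> None:
        if self.volume_mode not in ("baseline", "per_cycle"):
            raise DoseEngineError(f"unknown volume_mode {self.volume_mode!r}")


def _pick_timepoint(group: pd.DataFrame, t_h: float) -> pd.Series:
    """Row of the acquisition closest to t_h within a structure-cycle group."""
    idx = (group["t_h"] - t_h).abs().idxmin()
    return group.loc[idx]


def process_cohort(
    timepoints: pd.DataFrame,
    cf: CalibrationFactor,
    rc_curve: RecoveryCurve | None = None,
    config: EngineConfig | None = None,
) -> dict:
    """Run the full dose computation on a VOI time-point table.

    Per structure-cycle: cycles with >= 3 acquisitions get a monoexponential
    fit and closed-form integration; single-time-point cycles are scaled from
    the reference cycle's AD by the printed counts/volume ratios.  Lesion
    doses are PVE-corrected before summation into CumAD.

    Returns cycle_doses, structure cum_ad, patient lesion indices and a list
    of per-structure warnings.
    """
    config = config or EngineConfig()
    rc_curve = rc_curve or RecoveryCurve.identity()
    warnings: list[str] = []
    rows = []

    base_volume = (
        timepoints.sort_values(["cycle", "t_h"])
        .groupby(["patient_id", "structure_id"], sort=False)["volume_ml"]
        .first()
    )

    for (pid, sid), sgroup in timepoints.groupby(["patient_id", "structure_id"], sort=True):
        sclass = sgroup["structure_class"].iloc[0]
        cycles = sorted(sgroup["cycle"].unique())
        ref_ad = ref_counts = ref_volume = None
        for cyc in cycles:
            g = sgroup[sgroup["cycle"] == cyc]
            vol = (
                float(base_volume.loc[(pid, sid)])
                if config.volume_mode == "baseline"
                else float(g["volume_ml"].iloc[0])
            )
            dens = float(g["density_g_ml"].iloc[0])
            if len(g) >= config.min_timepoints_for_fit:
                dr = [
                    counts_to_doserate(
                        r.counts, r.duration_s, vol, dens, cf, config.led_constant_j
                    )
                    for r in g.itertuples()
                ]
                try:
                    fit = fit_monoexponential(
                        g["t_h"].to_numpy(),
                        dr,
                        refine=config.refine_fit,
                        strict_physical_floor=config.strict_physical_floor,
                    )
                except DoseEngineError as err:
                    warnings.append(f"{pid}/{sid} cycle {cyc}: fit failed ({err})")
                    continue
                if fit.below_physical:
                    warnings.append(
                        f"{pid}/{sid} cycle {cyc}: lambda_eff below physical decay constant"
                    )
                ad = integrate_monoexp(fit)
                method = "multi_timepoint"
                row24 = _pick_timepoint(g, config.stp_time_h)
                if cyc == config.reference_cycle:
                    ref_ad, ref_counts, ref_volume = ad, float(row24["counts"]), vol
            else:
                if ref_ad is None:
                    warnings.append(
                        f"{pid}/{sid} cycle {cyc}: no reference cycle for STP scaling; skipped"
                    )
                    continue
                row24 = _pick_timepoint(g, config.stp_time_h)
                ad = scale_single_timepoint(
                    ref_ad, float(row24["counts"]), ref_counts, ref_volume, vol
                )
                method = "single_timepoint_scaled"
            pve = sclass in config.pve_classes
            if pve:
                ad = apply_recovery_correction(ad, vol, rc_curve)
            rows.append(
                {
                    "patient_id": pid,
                    "cycle": int(cyc),
                    "structure_id": sid,
                    "structure_class": sclass,
                    "ad_gy": float(ad),
                    "method": method,
                    "pve_corrected": pve,
                }
            )

    cycle_doses = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "cycle", "structure_id", "structure_class",
            "ad_gy", "method", "pve_corrected",
        ],
    )

    cum_rows, idx_rows = [], []
    if len(cycle_doses):
        for pid, pgroup in cycle_doses.groupby("patient_id", sort=True):
            res = compute_course_dosimetry(pgroup)
            classes = pgroup.groupby("structure_id", sort=True)["structure_class"].first()
            for sid, cum in res["cum_ad"].items():
                cum_rows.append(
                    {
                        "patient_id": pid,
                        "structure_id": sid,
                        "structure_class": classes.loc[sid],
                        "cum_ad_gy": float(cum),
                    }
                )
            if res["indices"]:
                idx_rows.append({"patient_id": pid, **res["indices"]})
            else:
                warnings.append(f"{pid}: no lesions with doses; indices skipped")

    cum_ad = pd.DataFrame(
        cum_rows, columns=["patient_id", "structure_id", "structure_class", "cum_ad_gy"]
    )
    indices = pd.DataFrame(
        idx_rows,
        columns=["patient_id", "mean_total_ad", "min_total_ad", "max_total_ad", "n_lesions"],
    )
    return {
        "cycle_doses": cycle_doses,
        "cum_ad": cum_ad,
        "patient_indices": indices,
        "warnings": warnings,
    }
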
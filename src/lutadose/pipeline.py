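"""End-to-end orchestration, table schemas, validation and run manifests.

Stages: ``simulate`` (synthetic cohort) -> ``dose`` (VOI counts to absorbed
doses) -> ``respond`` (lesion selection and dV%) -> ``analyze``
(dose-response, TCP, toxicity, survival).  All interchange is CSV; the
statistics land in one JSON document; a manifest records config hash, file
checksums, row counts and warnings.  Identical config and seeds reproduce
identical output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dose_engine as de
from . import outcome_stats as st
from . import response_metrics as rm
from . import synthetic_cohort as sc

__version__ = "0.1.0"

log = logging.getLogger("lutadose")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


class PipelineError(RuntimeError):
    """A stage failed; the manifest records the failure point."""


class SchemaError(ValueError):
    """An input table violates its column contract."""


# --- table schemas ----------------------------------------------------------

#: column -> (dtype kind, constraint description)
SCHEMAS = {
    "timepoints": {
        "patient_id": "str",
        "cycle": "int",
        "structure_id": "str",
        "structure_class": "str",
        "t_h": "pos",
        "counts": "nonneg",
        "duration_s": "pos",
        "volume_ml": "pos",
        "density_g_ml": "pos",
    },
    "lesions": {
        "patient_id": "str",
        "lesion_id": "str",
        "site": "str",
        "v_bl_ml": "pos",
        "v_m3_ml": "nonneg_or_na",
    },
    "labs": {
        "patient_id": "str",
        "lab": "str",
        "baseline_value": "pos",
        "month3_value": "nonneg",
        "pct_change": "float",
    },
    "survival": {
        "patient_id": "str",
        "pfs_months": "pos",
        "pfs_event": "binary",
        "os_months": "pos",
        "os_event": "binary",
    },
    "calibration": {"cf_cps_per_mbq": "pos", "provenance": "str"},
    "rc": {"volume_ml": "pos", "rc": "pos"},
}

_UNIQUE_KEYS = {
    "timepoints": ["patient_id", "cycle", "structure_id", "t_h"],
    "lesions": ["lesion_id"],
    "survival": ["patient_id"],
}


def validate_table(df: pd.DataFrame, name: str) -> list[dict]:
    """Column and row-level violations of one table's schema."""
    schema = SCHEMAS[name]
    violations: list[dict] = []
    for col, kind in schema.items():
        if col not in df.columns:
            violations.append({"table": name, "row": None, "column": col,
                               "message": f"missing required column '{col}'"})
            continue
        s = df[col]
        if kind in ("pos", "nonneg", "nonneg_or_na", "float", "int", "binary"):
            vals = pd.to_numeric(s, errors="coerce")
            bad_numeric = vals.isna() & s.notna()
            if kind == "pos":
                bad = bad_numeric | (vals <= 0) | s.isna()
            elif kind == "nonneg":
                bad = bad_numeric | (vals < 0) | s.isna()
            elif kind == "nonneg_or_na":
                bad = bad_numeric | (vals < 0)
            elif kind == "binary":
                bad = bad_numeric | (~vals.isin([0, 1])) | s.isna()
            else:
                bad = bad_numeric
            for idx in df.index[bad.fillna(False)]:
                violations.append({"table": name, "row": int(idx), "column": col,
                                   "message": f"invalid {kind} value {df.loc[idx, col]!r}"})
        else:  # str
            for idx in df.index[s.isna() | (s.astype(str).str.len() == 0)]:
                violations.append({"table": name, "row": int(idx), "column": col,
                                   "message": "empty identifier"})
    key = _UNIQUE_KEYS.get(name)
    if key and all(c in df.columns for c in key):
        dup = df.duplicated(subset=key, keep="first")
        for idx in df.index[dup]:
            violations.append({"table": name, "row": int(idx), "column": "+".join(key),
                               "message": "duplicate key"})
    return violations


def validate_tables(paths: dict) -> pd.DataFrame:
    """Validate several CSVs; ``paths`` maps schema name -> file path."""
    all_v: list[dict] = []
    for name, path in paths.items():
        if name not in SCHEMAS:
            raise SchemaError(f"unknown table kind {name!r}")
        df = read_csv(path)
        all_v.extend(validate_table(df, name))
    return pd.DataFrame(all_v, columns=["table", "row", "column", "message"])


def require_valid(df: pd.DataFrame, name: str) -> pd.DataFrame:
    v = validate_table(df, name)
    if v:
        first = v[0]
        raise SchemaError(
            f"{name}: {len(v)} schema violation(s); first: column "
            f"'{first['column']}' row {first['row']}: {first['message']}"
        )
    return df


# --- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline configuration; YAML/JSON round-trippable."""

    out_dir: str = "run_out"
    seed: int = 0
    stages: tuple = ("simulate", "dose", "respond", "analyze")
    # simulate
    n_patients: int = 35
    noise_free: bool = False
    # dose
    led_constant_j: float = de.DEFAULT_LED_CONSTANT_J
    volume_mode: str = "baseline"
    refine_fit: bool = False
    # analyze
    n_boot: int = 1000
    # optional external inputs (used when 'simulate' is not in stages)
    timepoints_csv: str | None = None
    lesions_csv: str | None = None
    labs_csv: str | None = None
    survival_csv: str | None = None
    calibration_csv: str | None = None
    rc_csv: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return json.dumps(d, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_csv(path) -> pd.DataFrame:
    """CSV reader with round-trip float parsing so tables re-serialize byte-identically."""
    return pd.read_csv(path, float_precision="round_trip")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


# --- stages -----------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    cohort_cfg = sc.CohortConfig(
        n_patients=cfg.n_patients, noise_free=cfg.noise_free, seed=cfg.seed
    )
    tables = sc.generate_cohort(cohort_cfg)
    paths = tables.to_dir(out)
    cal = pd.DataFrame(
        {"cf_cps_per_mbq": [cohort_cfg.calibration_cps_per_mbq], "provenance": ["synthetic"]}
    )
    _write_csv(cal, out / "calibration.csv")
    _write_csv(cohort_cfg.rc_curve.to_frame(), out / "rc.csv")
    paths.update({"calibration": out / "calibration.csv", "rc": out / "rc.csv"})
    return {str(k): str(v) for k, v in paths.items()}


def _stage_dose(cfg: RunConfig, out: Path) -> dict:
    tp = require_valid(read_csv(cfg.timepoints_csv or out / "timepoints.csv"), "timepoints")
    cal = require_valid(
        read_csv(cfg.calibration_csv or out / "calibration.csv"), "calibration"
    )
    rc = require_valid(read_csv(cfg.rc_csv or out / "rc.csv"), "rc")
    res = de.process_cohort(
        tp,
        de.CalibrationFactor(float(cal["cf_cps_per_mbq"].iloc[0]),
                             str(cal["provenance"].iloc[0])),
        de.RecoveryCurve.from_frame(rc),
        de.EngineConfig(
            led_constant_j=cfg.led_constant_j,
            volume_mode=cfg.volume_mode,
            refine_fit=cfg.refine_fit,
        ),
    )
    _write_csv(res["cycle_doses"], out / "cycle_doses.csv")
    _write_csv(res["cum_ad"], out / "cum_ad.csv")
    _write_csv(res["patient_indices"], out / "patient_indices_all.csv")
    for w in res["warnings"]:
        log.warning("dose: %s", w)
    return {"warnings": res["warnings"],
            "n_cycle_doses": int(len(res["cycle_doses"]))}


def _stage_respond(cfg: RunConfig, out: Path) -> dict:
    lesions = require_valid(read_csv(cfg.lesions_csv or out / "lesions.csv"), "lesions")
    cum = read_csv(out / "cum_ad.csv")
    totals = cum[cum["structure_class"] == "lesion"][["structure_id", "cum_ad_gy"]]
    totals = totals.rename(columns={"structure_id": "lesion_id", "cum_ad_gy": "total_ad_gy"})
    lesions = lesions.merge(totals, on="lesion_id", how="left")
    selected = rm.select_lesions(lesions)
    analyzed = rm.add_response(selected)
    _write_csv(analyzed, out / "lesions_analyzed.csv")
    indices = rm.patient_dose_indices(analyzed.dropna(subset=["total_ad_gy"]))
    _write_csv(indices, out / "patient_dose_indices.csv")
    dropped = set(lesions["patient_id"]) - set(indices["patient_id"])
    warnings = [f"{p}: no selected lesions; excluded from dose indices"
                for p in sorted(dropped)]
    for w in warnings:
        log.warning("respond: %s", w)
    return {"warnings": warnings, "n_selected": int(analyzed["selected"].sum())}


def _stage_analyze(cfg: RunConfig, out: Path) -> dict:
    lesions = read_csv(out / "lesions_analyzed.csv")
    labs = require_valid(read_csv(cfg.labs_csv or out / "labs.csv"), "labs")
    surv = require_valid(read_csv(cfg.survival_csv or out / "survival.csv"), "survival")
    indices = read_csv(out / "patient_dose_indices.csv")
    cum = read_csv(out / "cum_ad.csv")

    fit_data = lesions[
        lesions["selected"] & lesions["delta_v_pct"].notna() & lesions["total_ad_gy"].notna()
    ]
    stats_out: dict = {"seed": cfg.seed, "n_boot": cfg.n_boot}

    dr = st.fit_dose_response(
        fit_data["total_ad_gy"], fit_data["delta_v_pct"], fit_data["patient_id"],
        n_boot=cfg.n_boot, seed=cfg.seed,
    )
    stats_out["dose_response"] = {
        "floor": dr.floor, "cap": dr.cap, "rate_per_gy": dr.rate, "n": dr.n,
        "ci": {k: list(v) for k, v in dr.ci.items()},
        "association_rho": dr.association_rho, "association_p": dr.association_p,
    }
    grid = np.linspace(0.0, float(fit_data["total_ad_gy"].max()), 100)
    _write_csv(pd.DataFrame({"total_ad_gy": grid, "delta_v_pct": dr.predict(grid)}),
               out / "dose_response_curve.csv")

    tcp = st.fit_tcp(fit_data["total_ad_gy"], fit_data["controlled"].astype(float))
    stats_out["tcp"] = {
        "intercept": tcp.intercept, "slope_per_gy": tcp.slope,
        "separation": tcp.separation, "method": tcp.method,
        "d50_gy": tcp.d50_gy, "d90_gy": tcp.d90_gy,
    }
    _write_csv(pd.DataFrame({"total_ad_gy": grid, "tcp": tcp.predict(grid)}),
               out / "tcp_curve.csv")

    organ_cum = cum[cum["structure_class"] != "lesion"]
    pairs = []
    for organ in ("bone_marrow", "spleen", "kidneys"):
        od = organ_cum[organ_cum["structure_id"] == organ][["patient_id", "cum_ad_gy"]]
        merged = labs.merge(od, on="patient_id", how="inner")
        for lab in sorted(merged["lab"].unique()):
            sub = merged[merged["lab"] == lab]
            pairs.append(pd.DataFrame({
                "organ": organ, "lab": lab,
                "cum_ad_gy": sub["cum_ad_gy"].to_numpy(),
                "pct_change": sub["pct_change"].to_numpy(),
            }))
    tox = st.correlate_toxicity(pd.concat(pairs, ignore_index=True))
    _write_csv(tox, out / "toxicity_correlations.csv")
    stats_out["toxicity"] = tox.to_dict(orient="records")

    marrow = organ_cum[organ_cum["structure_id"] == "bone_marrow"][["patient_id", "cum_ad_gy"]]
    plat = labs[labs["lab"] == "platelets"].merge(marrow, on="patient_id")
    _write_csv(st.loess_trend(plat["cum_ad_gy"], plat["pct_change"]),
               out / "loess_marrow_platelets.csv")

    lab_tests = {}
    for lab in sorted(labs["lab"].unique()):
        sub = labs[labs["lab"] == lab]
        lab_tests[lab] = st.paired_lab_test(sub["baseline_value"], sub["month3_value"])
    stats_out["paired_lab_tests"] = lab_tests

    sdf = surv.merge(indices, on="patient_id", how="inner")
    km_frames = []
    stats_out["survival"] = {}
    for cov in ("mean_total_ad", "min_total_ad", "max_total_ad"):
        for endpoint, tcol, ecol in (("pfs", "pfs_months", "pfs_event"),
                                     ("os", "os_months", "os_event")):
            comp = st.survival_by_median(
                sdf[cov], sdf[tcol], sdf[ecol], endpoint=endpoint, covariate_name=cov
            )
            stats_out["survival"][f"{endpoint}_by_{cov}"] = {
                "median_cut_gy": comp.median_cut,
                "n_high": comp.n_high, "n_low": comp.n_low,
                "hazard_ratio": comp.hazard_ratio,
                "hr_ci": list(comp.hr_ci) if comp.hr_ci else None,
                "hr_p": comp.hr_p, "logrank_p": comp.logrank_p,
                "median_high": comp.median_high, "median_low": comp.median_low,
                "hr_estimable": comp.hr_estimable,
            }
            kc = comp.km_curves.copy()
            kc.insert(0, "analysis", f"{endpoint}_by_{cov}")
            km_frames.append(kc)
    _write_csv(pd.concat(km_frames, ignore_index=True), out / "km_curves.csv")

    (out / "statistics.json").write_text(json.dumps(stats_out, sort_keys=True, indent=1))
    return {"n_analyses": len(stats_out["survival"]) + 3}


# --- orchestration ----------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Run the toggled stages in order and write a run manifest.

    Returns the manifest dict; raises PipelineError after recording a stage
    failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(config.to_canonical_json().encode()).hexdigest(),
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "checksums": {},
        "row_counts": {},
    }
    stage_fns = {
        "simulate": _stage_simulate,
        "dose": _stage_dose,
        "respond": _stage_respond,
        "analyze": _stage_analyze,
    }
    failure = None
    for stage in config.stages:
        if stage not in stage_fns:
            raise PipelineError(f"unknown stage {stage!r}")
        log.info("stage %s", stage)
        t0 = time.time()
        try:
            info = stage_fns[stage](config, out)
            manifest["stages"][stage] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 3),
                **{k: v for k, v in (info or {}).items() if k != "warnings"},
                "warnings": (info or {}).get("warnings", []),
            }
        except Exception as err:  # recorded, then surfaced
            manifest["stages"][stage] = {"status": "failed", "error": str(err)}
            failure = (stage, err)
            break
    for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if p.name == "manifest.json":
            continue
        manifest["checksums"][p.name] = _sha256(p)
        if p.suffix == ".csv":
            with open(p) as fh:
                manifest["row_counts"][p.name] = max(sum(1 for _ in fh) - 1, 0)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    if failure:
        raise PipelineError(f"stage {failure[0]} failed: {failure[1]}") from failure[1]
    return manifest
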
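"""Lesion selection rules and per-lesion response metrics.

Target lesions are selected per patient and site: bone lesions are excluded
(response not assessable), lesions under 2 cm3 are excluded (partial-volume
effect dominates; RC ~ 0.5 at that volume), and at most 5 lesions per site
are kept, always including the site's largest and smallest.  Response is the
percent volume change between the baseline CT and the CT three months after
the last cycle:

    dV% = 100 * (V_m3 - V_bl) / V_bl

A lesion is "controlled" when dV% <= 0 and "stable" when dV% <= +20
(an increase strictly above 20% breaks stability); controlled implies stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Default selection thresholds.
MIN_LESION_VOLUME_ML = 2.0
MAX_LESIONS_PER_SITE = 5
EXCLUDED_SITES = ("bone",)
STABLE_THRESHOLD_PCT = 20.0
CONTROLLED_THRESHOLD_PCT = 0.0


class ResponseError(ValueError):
    """Invalid response-metric input."""


def compute_delta_v(v_bl_ml: float, v_m3_ml: float) -> float:
    """Percent lesion-volume change from baseline to month 3; negative = shrinkage."""
    if v_bl_ml <= 0:
        raise ResponseError("baseline volume must be > 0")
    if v_m3_ml < 0:
        raise ResponseError("follow-up volume must be >= 0")
    return 100.0 * (v_m3_ml - v_bl_ml) / v_bl_ml


@dataclass(frozen=True)
class ResponseResult:
    delta_v_pct: float
    controlled: bool
    stable: bool


def classify_response(delta_v_pct: float) -> ResponseResult:
    """Controlled (dV% <= 0) and stable (dV% <= +20) flags; bounds inclusive."""
    if delta_v_pct < -100.0 - 1e-9:
        raise ResponseError("dV% below -100 implies a negative follow-up volume")
    controlled = delta_v_pct <= CONTROLLED_THRESHOLD_PCT
    stable = delta_v_pct <= STABLE_THRESHOLD_PCT
    return ResponseResult(float(delta_v_pct), controlled, stable)


def select_lesions(
    candidates: pd.DataFrame,
    min_volume_ml: float = MIN_LESION_VOLUME_ML,
    max_per_site: int = MAX_LESIONS_PER_SITE,
    excluded_sites: tuple = EXCLUDED_SITES,
) -> pd.DataFrame:
    """Apply the lesion-selection rules; returns a copy with flags.

    Adds ``selected`` and ``exclusion_reason`` columns.  When more than
    ``max_per_site`` lesions survive at one site, the largest and smallest
    are kept unconditionally and the remaining slots are filled by
    descending volume (ties by lesion_id).  Idempotent: re-selecting a
    selected table changes nothing.
    """
    df = candidates.copy()
    for col in ("patient_id", "lesion_id", "site", "v_bl_ml"):
        if col not in df.columns:
            raise ResponseError(f"lesion table missing column {col!r}")
    df["selected"] = True
    df["exclusion_reason"] = ""

    bone = df["site"].isin(excluded_sites)
    df.loc[bone, ["selected", "exclusion_reason"]] = [False, "bone_site"]
    small = (~bone) & (df["v_bl_ml"] < min_volume_ml)
    df.loc[small, ["selected", "exclusion_reason"]] = [False, "small_volume"]

    for (_, _), group in df[df["selected"]].groupby(["patient_id", "site"], sort=False):
        if len(group) <= max_per_site:
            continue
        ordered = group.sort_values(
            ["v_bl_ml", "lesion_id"], ascending=[False, True], kind="mergesort"
        )
        keep = [ordered.index[0], ordered.index[-1]]  # site max and min volumes
        for idx in ordered.index[1:-1]:
            if len(keep) >= max_per_site:
                break
            keep.append(idx)
        drop = group.index.difference(keep)
        df.loc[drop, ["selected", "exclusion_reason"]] = [False, "site_cap"]
    return df


def add_response(lesions: pd.DataFrame) -> pd.DataFrame:
    """Attach delta_v_pct / controlled / stable columns.

    Lesions without a follow-up volume get NaN response and a
    ``missing_followup`` flag; they stay usable for dose indices but are
    excluded from dose-response fitting.
    """
    df = lesions.copy()
    missing = df["v_m3_ml"].isna()
    dv = np.full(len(df), np.nan)
    ok = ~missing
    dv[ok.to_numpy()] = [
        compute_delta_v(b, m)
        for b, m in zip(df.loc[ok, "v_bl_ml"], df.loc[ok, "v_m3_ml"])
    ]
    df["delta_v_pct"] = dv
    df["missing_followup"] = missing
    df["controlled"] = pd.array(df["delta_v_pct"] <= CONTROLLED_THRESHOLD_PCT, dtype="boolean")
    df["stable"] = pd.array(df["delta_v_pct"] <= STABLE_THRESHOLD_PCT, dtype="boolean")
    df.loc[missing, ["controlled", "stable"]] = pd.NA
    return df


def patient_dose_indices(selected_lesions: pd.DataFrame) -> pd.DataFrame:
    """Mean / Min / Max of total lesion AD per patient over selected lesions.

    Patients with zero selected lesions are dropped (the caller sees them in
    the returned frame's absence; a warning is the pipeline's job).
    """
    if "total_ad_gy" not in selected_lesions.columns:
        raise ResponseError("lesion table missing column 'total_ad_gy'")
    sel = selected_lesions
    if "selected" in sel.columns:
        sel = sel[sel["selected"]]
    grouped = sel.groupby("patient_id", sort=True)["total_ad_gy"]
    out = grouped.agg(
        mean_total_ad="mean", min_total_ad="min", max_total_ad="max", n_lesions="count"
    ).reset_index()
    return out
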
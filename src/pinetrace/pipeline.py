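"""High-level analysis chains over a campaign table.

These helpers wire the per-module operations into the study's standard
analyses: needle uptake and residence time, soil-CO2 arrival lag and
transport velocity, PLFA community summaries and fungal label peak, and
fraction-of-label accounting. Each consumes a typed CampaignTable, never a
file, and returns tidy DataFrames ready for treatment-level summaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import plfa as plfa_mod
from .data import CampaignTable, summarize_by_treatment
from .efflux import EffluxParams, efflux_series
from .isotope import ExcessSeries, build_excess_series
from .kinetics import (ExponentialDecayModel, NonDecayingSeriesError,
                       cumulative_released, detect_arrival, fraction_allocated,
                       peak_time, transport_velocity)
from .simulate import T45

log = logging.getLogger("pinetrace")


def needle_kinetics(table: CampaignTable) -> pd.DataFrame:
    """Per-mesocosm needle label uptake and mean residence time.

    Uptake is the 13C excess at the 45-min sample (the labelling peak);
    the residence time comes from the first-order washout fit from that
    peak onward. Mesocosms whose series does not decay are flagged with a
    null tau rather than dropped.
    """
    rows = []
    for mid in table.mesocosm_ids():
        series = build_excess_series(table, "needle", mid)
        post = series.after(0.0)
        i45 = int(np.argmin(np.abs(post.times - T45)))
        row = {"mesocosm_id": mid,
               "treatment": table.mesocosms[mid].treatment,
               "excess_45min_mg13c_m2": float(post.values[i45])}
        try:
            res = ExponentialDecayModel(series).fit()
            row.update(tau_d=res.tau, lambda_per_d=res.lam, n0_mg13c_m2=res.n0,
                       rss=res.rss, n_points=res.n_points)
        except NonDecayingSeriesError as err:
            log.warning("mesocosm %s: %s", mid, err)
            row.update(tau_d=np.nan, lambda_per_d=np.nan,
                       n0_mg13c_m2=np.nan, rss=np.nan, n_points=0)
        rows.append(row)
    return pd.DataFrame(rows)


def _gas_delta_series(table: CampaignTable, mesocosm_id: str) -> ExcessSeries:
    """Soil-pore delta13C series of one mesocosm."""
    df = table.measurements
    sub = df[(df["compartment"] == "soil_pore_co2")
             & (df["mesocosm_id"] == mesocosm_id)
             & df["delta13c_permil"].notna()].sort_values("time_d")
    return ExcessSeries("soil_pore_co2", mesocosm_id,
                        sub["time_d"].to_numpy(),
                        sub["delta13c_permil"].to_numpy(), "pool")


def _gas_baseline_stats(table: CampaignTable):
    """Natural background of soil-pore delta13C and its measurement SD.

    The background mean pools all pre-label gas samples in the campaign
    (the natural 13C abundance of soil CO2 is a property of the shared
    soil, and per-treatment pre-label samples are few). The single-sample
    SD is the median of the replicate SDs of the mesocosms within a
    treatment at each sampling time, taken over all treatments and times
    and debiased for the small replicate count; the median keeps the
    estimate insensitive to times where between-tree differences in the
    arrived signal dominate the spread.
    """
    from scipy.stats import chi2

    df = table.measurements
    gas = df[(df["compartment"] == "soil_pore_co2")
             & df["delta13c_permil"].notna()]
    pre = gas[gas["time_d"] < 0]
    if pre.empty:
        raise ValueError("no pre-label soil-pore gas samples")
    sds, dofs = [], []
    for _, grp in gas.groupby(["treatment", "time_d"]):
        v = grp["delta13c_permil"].to_numpy()
        if v.size >= 2:
            sds.append(float(np.std(v, ddof=1)))
            dofs.append(v.size - 1)
    if not sds:
        return float(pre["delta13c_permil"].mean()), 0.0
    dof = int(np.median(dofs))
    debias = np.sqrt(chi2.ppf(0.5, dof) / dof)  # median of s/sigma at this dof
    return float(pre["delta13c_permil"].mean()), float(np.median(sds) / debias)


def transport_summary(table: CampaignTable, k: float = 3.0) -> pd.DataFrame:
    """Arrival lag and per-tree transport velocity, by treatment.

    The 13C arrival is detected on each mesocosm's soil-pore delta13C
    series (threshold: pooled pre-label background + k SD, persisting at
    the next sample); the treatment lag is the median across its
    mesocosms, and each tree's velocity is its own height divided by that
    treatment lag.
    """
    mean, sd = _gas_baseline_stats(table)
    rows = []
    for trt in dict.fromkeys(table.treatment_of.values()):
        lags = []
        for mid in table.mesocosm_ids(trt):
            lag = detect_arrival(_gas_delta_series(table, mid), mean, sd, k=k)
            if lag:
                lags.append(lag.lag_days)
        trt_lag = float(np.median(lags)) if lags else np.nan
        for mid in table.mesocosm_ids(trt):
            h = table.mesocosms[mid].tree_height_cm
            v = (transport_velocity(h, trt_lag).velocity_cm_d
                 if np.isfinite(trt_lag) else np.nan)
            rows.append({"mesocosm_id": mid, "treatment": trt,
                         "tree_height_cm": h, "arrival_lag_d": trt_lag,
                         "velocity_cm_d": v})
    return pd.DataFrame(rows)


def excess_long_table(table: CampaignTable, compartments=("needle", "fine_root"),
                      efflux_params: EffluxParams = None) -> pd.DataFrame:
    """Long table of 13C excess per compartment x mesocosm x time.

    ``soil_pore_co2`` entries need efflux parameters (the modelled flux
    supplies the rate conversion) and yield mg 13C m-2 h-1; tissue entries
    yield mg 13C m-2.
    """
    frames = []
    for mid in table.mesocosm_ids():
        env_m = table.environment[table.environment["mesocosm_id"] == mid]
        for comp in compartments:
            if comp == "soil_pore_co2":
                if efflux_params is None:
                    raise ValueError("soil_pore_co2 excess needs efflux_params")
                flux_model = (lambda t, e=env_m:
                              efflux_series(efflux_params, e, t))
                s = build_excess_series(table, comp, mid, flux_model=flux_model)
                col = "excess_mg13c_m2_h"
            else:
                s = build_excess_series(table, comp, mid)
                col = "excess_mg13c_m2"
            frames.append(pd.DataFrame({
                "mesocosm_id": mid,
                "treatment": table.mesocosms[mid].treatment,
                "compartment": comp, "time_d": s.times, col: s.values}))
    return pd.concat(frames, ignore_index=True)


def released_label(table: CampaignTable, efflux_params: EffluxParams,
                   t0: float = 0.0, t1: float = 14.0) -> pd.DataFrame:
    """Cumulative 13C released via soil CO2 efflux over [t0, t1], mg m-2."""
    rows = []
    for mid in table.mesocosm_ids():
        env_m = table.environment[table.environment["mesocosm_id"] == mid]
        s = build_excess_series(
            table, "soil_pore_co2", mid,
            flux_model=lambda t, e=env_m: efflux_series(efflux_params, e, t))
        rows.append({"mesocosm_id": mid,
                     "treatment": table.mesocosms[mid].treatment,
                     "released_mg13c_m2": cumulative_released(s, t0, t1)})
    return pd.DataFrame(rows)


def allocation_fractions(table: CampaignTable, efflux_params: EffluxParams = None,
                         t1: float = 14.0) -> pd.DataFrame:
    """Fraction of the assimilated label in each belowground compartment.

    Normalizes by the needle 13C excess at 45 min (the maximum needle
    excess) per mesocosm: fine-root fraction at its latest sample <= t1,
    released fraction integrated over [0, t1], and the fungal PLFA group
    fraction at its peak.
    """
    kin = needle_kinetics(table).set_index("mesocosm_id")
    rows = []
    for mid in table.mesocosm_ids():
        ref = kin.loc[mid, "excess_45min_mg13c_m2"]
        row = {"mesocosm_id": mid,
               "treatment": table.mesocosms[mid].treatment,
               "needle_reference_mg13c_m2": ref}
        root = build_excess_series(table, "fine_root", mid)
        frac = fraction_allocated(root, ref)
        in_win = frac.after(0.0)
        sel = in_win.times <= t1
        row["fine_root_fraction"] = float(in_win.values[sel][-1])
        _, groups = plfa_mod.plfa_excess(table, mid)
        if "fungi" in groups:
            ffrac = fraction_allocated(groups["fungi"], ref)
            row["fungal_fraction"] = float(np.max(ffrac.after(0.0).values))
        if efflux_params is not None:
            env_m = table.environment[table.environment["mesocosm_id"] == mid]
            s = build_excess_series(
                table, "soil_pore_co2", mid,
                flux_model=lambda t, e=env_m: efflux_series(efflux_params, e, t))
            row["released_fraction"] = cumulative_released(s, 0.0, t1) / ref
        rows.append(row)
    return pd.DataFrame(rows)


def plfa_treatment_summary(table: CampaignTable) -> pd.DataFrame:
    """Community ratios and group totals per treatment (mean +/- SE).

    Each mesocosm x sampling time profile is summarized, averaged within
    mesocosm, then summarized across mesocosms per treatment.
    """
    prof = plfa_mod.plfa_profiles(table)
    per_profile = []
    for (mid, t), grp in prof.groupby(["mesocosm_id", "time_d"]):
        gs = plfa_mod.group_summary(grp.rename(columns={})[
            ["compound", "conc_ug_gdw"]])
        per_profile.append({"mesocosm_id": mid, "time_d": t,
                            "fb_ratio": gs.fb_ratio,
                            "gp_gn_ratio": gs.gp_gn_ratio,
                            "total_bacteria": gs.total_bacteria,
                            "actinobacteriota": gs.totals["actinobacteriota"],
                            "fungi": gs.totals["fungi"],
                            "total_all": gs.total_all})
    pp = pd.DataFrame(per_profile)
    per_meso = pp.groupby("mesocosm_id").mean(numeric_only=True)
    out = []
    for col in ("fb_ratio", "gp_gn_ratio", "total_bacteria",
                "actinobacteriota", "fungi", "total_all"):
        s = summarize_by_treatment(per_meso[col].to_dict(), table.treatment_of)
        s.insert(0, "quantity", col)
        out.append(s.reset_index())
    return pd.concat(out, ignore_index=True)


def fungal_peak_day(table: CampaignTable, treatment: str) -> float:
    """Sampled day of maximum treatment-mean fungal PLFA 13C excess."""
    series = []
    for mid in table.mesocosm_ids(treatment):
        _, groups = plfa_mod.plfa_excess(table, mid)
        series.append(groups["fungi"])
    times = series[0].times
    mean = np.mean([s.values for s in series], axis=0)
    return peak_time(ExcessSeries("plfa_group:fungi", f"<{treatment} mean>",
                                  times, mean, "pool").after(0.0))


def efflux_peak_day(table: CampaignTable, treatment: str,
                    efflux_params: EffluxParams) -> float:
    """Sampled day of maximum treatment-mean released-label rate."""
    series = []
    for mid in table.mesocosm_ids(treatment):
        env_m = table.environment[table.environment["mesocosm_id"] == mid]
        series.append(build_excess_series(
            table, "soil_pore_co2", mid,
            flux_model=lambda t, e=env_m: efflux_series(efflux_params, e, t)))
    times = series[0].times
    mean = np.mean([s.values for s in series], axis=0)
    return peak_time(ExcessSeries("soil_pore_co2", f"<{treatment} mean>",
                                  times, mean, "rate").after(0.0))


def pore_co2_summary(table: CampaignTable) -> pd.DataFrame:
    """Mean +/- SE soil pore CO2 concentration (ppm) per treatment."""
    df = table.measurements
    sub = df[(df["compartment"] == "soil_pore_co2") & df["co2_ppm"].notna()]
    per_meso = sub.groupby("mesocosm_id")["co2_ppm"].mean()
    return summarize_by_treatment(per_meso.to_dict(), table.treatment_of)
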
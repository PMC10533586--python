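"""Soil CO2 efflux as a function of temperature and moisture.

The efflux entering the released-label calculation is modelled as a Q10
temperature response times a Michaelis-type moisture scalar,

    F(T, theta) = f_ref * q10^((T - t_ref)/10) * theta / (k_theta + theta),

with T in deg C and theta the volumetric water content in percent. The
functional form sits behind a single predict interface so an alternative
temperature-moisture response can be swapped in without touching the rest
of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["EffluxParams", "predict_efflux", "EffluxModel", "EffluxResults",
           "DegenerateDesignError", "efflux_series"]

#: Reference temperature, deg C. Fixed (not fitted) to avoid f_ref/t_ref
#: confounding; a greenhouse-relevant midpoint.
T_REF_DEFAULT = 20.0


class DegenerateDesignError(ValueError):
    """Calibration data cannot identify the parameters (single T or VWC)."""


@dataclass
class EffluxParams:
    """Parameters of the temperature-moisture efflux response.

    f_ref : flux at t_ref under non-limiting moisture, mg C m-2 h-1
    q10 : multiplicative response to a 10 deg C warming (unitless)
    k_theta : half-saturation of the moisture scalar, % VWC
    """

    f_ref: float
    q10: float
    k_theta: float
    t_ref: float = T_REF_DEFAULT

    def __post_init__(self):
        if self.f_ref < 0 or self.q10 <= 0 or self.k_theta <= 0:
            raise ValueError("require f_ref >= 0, q10 > 0, k_theta > 0")

    def to_dict(self):
        return {"f_ref": self.f_ref, "q10": self.q10,
                "k_theta": self.k_theta, "t_ref": self.t_ref}


def predict_efflux(params: EffluxParams, t_c, vwc_pct):
    """Modelled CO2 efflux, mg C m-2 h-1. Monotone increasing in T and VWC."""
    t = np.asarray(t_c, dtype=float)
    theta = np.asarray(vwc_pct, dtype=float)
    f = (params.f_ref * params.q10 ** ((t - params.t_ref) / 10.0)
         * theta / (params.k_theta + theta))
    return f if f.ndim else float(f)


@dataclass
class EffluxResults:
    """Calibrated efflux parameters with uncertainties and diagnostics."""

    params: EffluxParams
    bse: dict
    rss: float
    n_obs: int

    def predict(self, t_c, vwc_pct):
        return predict_efflux(self.params, t_c, vwc_pct)

    def summary(self) -> str:
        p, b = self.params, self.bse
        return "\n".join([
            "Soil CO2 efflux calibration  F = f_ref q10^((T-t_ref)/10) "
            "theta/(k_theta+theta)",
            f"  n obs   : {self.n_obs}",
            f"  f_ref   = {p.f_ref:9.3f} +/- {b['f_ref']:.3f}  mg C m-2 h-1",
            f"  q10     = {p.q10:9.3f} +/- {b['q10']:.3f}",
            f"  k_theta = {p.k_theta:9.3f} +/- {b['k_theta']:.3f}  % VWC",
            f"  t_ref   = {p.t_ref:9.3f}  deg C (fixed)",
            f"  RSS     = {self.rss:.6g}",
        ])


class EffluxModel:
    """Least-squares calibration of the efflux response to observations.

    Parameters
    ----------
    flux : array_like, mg C m-2 h-1
    temp_c, vwc_pct : array_like
        Paired soil temperature and volumetric water content.
    t_ref : float
        Reference temperature, excluded from fitting.
    """

    def __init__(self, flux, temp_c, vwc_pct, t_ref: float = T_REF_DEFAULT):
        self.flux = np.asarray(flux, dtype=float)
        self.temp = np.asarray(temp_c, dtype=float)
        self.vwc = np.asarray(vwc_pct, dtype=float)
        if not (self.flux.shape == self.temp.shape == self.vwc.shape):
            raise ValueError("flux, temp and vwc must be paired")
        if np.any(self.flux < 0):
            raise ValueError("fluxes must be >= 0")
        if self.flux.size < 4:
            raise DegenerateDesignError("need >= 4 paired observations")
        if np.ptp(self.temp) < 0.5:
            raise DegenerateDesignError(
                "single-temperature design: q10 unidentifiable")
        if np.ptp(self.vwc) < 0.5:
            raise DegenerateDesignError(
                "single-moisture design: k_theta unidentifiable")
        self.t_ref = t_ref

    @classmethod
    def from_dataframe(cls, obs: pd.DataFrame, env: pd.DataFrame,
                       t_ref: float = T_REF_DEFAULT) -> "EffluxModel":
        """Pair flux observations with the environment record in time.

        ``obs`` needs columns mesocosm_id, time_d, flux_mg_c_m2_h; ``env``
        follows the environment contract. Temperature and moisture are
        interpolated linearly in time per mesocosm.
        """
        flux, temp, vwc = [], [], []
        for mid, grp in obs.groupby("mesocosm_id"):
            e = env[env["mesocosm_id"] == mid].sort_values("time_d")
            if e.empty:
                raise ValueError(f"no environment record for mesocosm {mid!r}")
            t = grp["time_d"].to_numpy(dtype=float)
            flux.append(grp["flux_mg_c_m2_h"].to_numpy(dtype=float))
            temp.append(np.interp(t, e["time_d"], e["soil_temp_c"]))
            vwc.append(np.interp(t, e["time_d"], e["vwc_pct"]))
        return cls(np.concatenate(flux), np.concatenate(temp),
                   np.concatenate(vwc), t_ref=t_ref)

    def fit(self, p0=(50.0, 2.0, 10.0)) -> EffluxResults:
        t_ref = self.t_ref

        def model(x, f_ref, q10, k_theta):
            t, theta = x
            return f_ref * q10 ** ((t - t_ref) / 10.0) * theta / (k_theta + theta)

        try:
            popt, pcov = curve_fit(
                model, (self.temp, self.vwc), self.flux, p0=p0,
                bounds=([0.0, 0.1, 1e-3], [np.inf, 10.0, 1e3]),
                maxfev=20000, xtol=1e-12, ftol=1e-12)
        except RuntimeError as err:
            raise RuntimeError(f"efflux calibration did not converge: {err}")
        resid = self.flux - model((self.temp, self.vwc), *popt)
        bse = dict(zip(("f_ref", "q10", "k_theta"), np.sqrt(np.diag(pcov))))
        params = EffluxParams(f_ref=float(popt[0]), q10=float(popt[1]),
                              k_theta=float(popt[2]), t_ref=t_ref)
        return EffluxResults(params=params, bse={k: float(v) for k, v in bse.items()},
                             rss=float(resid @ resid), n_obs=self.flux.size)


def efflux_series(params: EffluxParams, env: pd.DataFrame, times_d):
    """Evaluate the model on a monitoring record at given sampling times.

    Environment covariates are interpolated linearly in time; times outside
    the monitored window are an error (no extrapolation).
    """
    times = np.asarray(times_d, dtype=float)
    e = env.sort_values("time_d")
    t_env = e["time_d"].to_numpy(dtype=float)
    if times.min() < t_env.min() or times.max() > t_env.max():
        raise ValueError("sampling schedule extends beyond the environment record")
    temp = np.interp(times, t_env, e["soil_temp_c"])
    vwc = np.interp(times, t_env, e["vwc_pct"])
    return predict_efflux(params, temp, vwc)
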
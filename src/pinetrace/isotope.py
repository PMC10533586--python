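"""Stable-isotope arithmetic for :sup:`13`\\ C tracer accounting.

All quantities follow the conventions of compound- and tissue-level IRMS
work: isotopic composition is expressed in delta notation (per mil, VPDB),
converted to atom% :sup:`13`\\ C, and the tracer content of a compartment is
the *excess* above its own pre-label background:

    excess (mg 13C m-2)       = enrichment * C pool (mg C m-2)
    excess rate (mg m-2 h-1)  = enrichment * CO2 efflux (mg C m-2 h-1)

where enrichment = (atom%_labelled - atom%_background) / 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Accepted 13C/12C isotope ratio of the VPDB standard.
R_VPDB = 0.0111802

__all__ = [
    "R_VPDB",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "enrichment",
    "carbon_pool",
    "excess_allocated",
    "excess_released",
    "ExcessSeries",
    "build_excess_series",
]


def delta_to_atom_percent(delta):
    """Convert delta13C (per mil VPDB) to atom% 13C.

    atom% = 100 / (1 / ((delta/1000 + 1) * R_VPDB) + 1)

    Strictly increasing in delta; delta = -1000 (no 13C) maps to 0.

    Parameters
    ----------
    delta : float or array_like
        delta13C in per mil relative to VPDB. Must be >= -1000.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < -1000.0):
        raise ValueError("delta13C below -1000 permil is unphysical")
    ratio = (delta / 1000.0 + 1.0) * R_VPDB
    ap = 100.0 * ratio / (1.0 + ratio)
    return ap if ap.ndim else float(ap)


def atom_percent_to_delta(atom_percent):
    """Exact algebraic inverse of :func:`delta_to_atom_percent`.

    Defined for 0 <= atom% < 100 (atom% = 100 would require an infinite
    13C/12C ratio).
    """
    ap = np.asarray(atom_percent, dtype=float)
    if np.any(ap < 0.0) or np.any(ap >= 100.0):
        raise ValueError("atom%% must lie in [0, 100)")
    ratio = ap / (100.0 - ap)
    delta = (ratio / R_VPDB - 1.0) * 1000.0
    return delta if delta.ndim else float(delta)


def enrichment(atom_percent_labelled, atom_percent_background):
    """13C enrichment: (atom%_l - atom%_n) / 100, a unitless tracer fraction.

    The background must come from a pre-label sample of the same
    compartment and mesocosm; there is deliberately no global default.
    """
    apl = np.asarray(atom_percent_labelled, dtype=float)
    apn = np.asarray(atom_percent_background, dtype=float)
    e = (apl - apn) / 100.0
    return e if e.ndim else float(e)


def carbon_pool(biomass_areal_g_m2, carbon_pct):
    """Tissue carbon pool in mg C m-2 ground area.

    Parameters
    ----------
    biomass_areal_g_m2 : float
        Dry weight per ground area (g m-2).
    carbon_pct : float
        Carbon concentration of the tissue in percent of dry weight.
    """
    b = np.asarray(biomass_areal_g_m2, dtype=float)
    c = np.asarray(carbon_pct, dtype=float)
    if np.any(b < 0) or np.any(c < 0) or np.any(c > 100):
        raise ValueError("biomass must be >= 0 and carbon percent in [0, 100]")
    pool = b * 1000.0 * c / 100.0
    return pool if pool.ndim else float(pool)


def excess_allocated(enrichment_value, pool_mg_c_m2):
    """13C excess allocated to a compartment, mg 13C m-2 (enrichment x pool)."""
    p = np.asarray(pool_mg_c_m2, dtype=float)
    if np.any(p < 0):
        raise ValueError("carbon pool must be >= 0")
    out = np.asarray(enrichment_value, dtype=float) * p
    return out if out.ndim else float(out)


def excess_released(enrichment_value, co2_efflux_mg_c_m2_h):
    """13C excess released as soil CO2, mg 13C m-2 h-1 (enrichment x efflux)."""
    f = np.asarray(co2_efflux_mg_c_m2_h, dtype=float)
    if np.any(f < 0):
        raise ValueError("CO2 efflux must be >= 0")
    out = np.asarray(enrichment_value, dtype=float) * f
    return out if out.ndim else float(out)


@dataclass
class ExcessSeries:
    """Time-resolved 13C excess of one compartment in one mesocosm.

    ``kind`` distinguishes pool series (mg 13C m-2) from rate series
    (mg 13C m-2 h-1, soil CO2 efflux). Times are days since the end of the
    labelling window; negative times are pre-label baselines.
    """

    compartment: str
    mesocosm_id: str
    times: np.ndarray
    values: np.ndarray
    kind: str = "pool"  # "pool" | "rate"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have matching shapes")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.kind not in ("pool", "rate"):
            raise ValueError(f"unknown series kind {self.kind!r}")

    def __len__(self):
        return self.times.size

    def after(self, t0: float) -> "ExcessSeries":
        """Sub-series restricted to times >= t0."""
        m = self.times >= t0
        return ExcessSeries(self.compartment, self.mesocosm_id,
                            self.times[m], self.values[m], self.kind, dict(self.meta))

    def scaled(self, factor: float) -> "ExcessSeries":
        return ExcessSeries(self.compartment, self.mesocosm_id,
                            self.times, self.values * factor, self.kind, dict(self.meta))


class MissingBaselineError(ValueError):
    """No pre-label observation available to define the natural background."""


def _baseline_atom_percent(sub):
    pre = sub[sub["time_d"] < 0]
    if pre.empty or pre["delta13c_permil"].dropna().empty:
        raise MissingBaselineError(
            "no pre-label baseline observation for this compartment/mesocosm")
    return float(np.mean(delta_to_atom_percent(pre["delta13c_permil"].dropna().to_numpy())))


def build_excess_series(table, compartment, mesocosm_id, flux_model=None):
    """Chain delta -> atom% -> enrichment -> excess over a sampling campaign.

    For tissue compartments (``needle``, ``fine_root``) the C pool at each
    sampling time is taken from the biomass and %C measured nearest in time
    (no interpolation). For ``soil_pore_co2`` a ``flux_model`` callable
    ``t_days -> mg C m-2 h-1`` must be supplied and the result is a rate
    series. The atom% background is the mean over the mesocosm's own
    pre-label samples.

    Parameters
    ----------
    table : CampaignTable
    compartment : str
    mesocosm_id : str
    flux_model : callable, optional
        Modelled CO2 efflux evaluated at the gas sampling times.

    Returns
    -------
    ExcessSeries
        Includes the pre-label points, whose excess is ~0 by construction.
    """
    df = table.measurements
    sub = df[(df["compartment"] == compartment)
             & (df["mesocosm_id"] == mesocosm_id)].sort_values("time_d")
    if sub.empty:
        raise ValueError(f"no measurements for {compartment!r} in {mesocosm_id!r}")
    ap_n = _baseline_atom_percent(sub)

    sub = sub.dropna(subset=["delta13c_permil"])
    t = sub["time_d"].to_numpy(dtype=float)
    e = enrichment(delta_to_atom_percent(sub["delta13c_permil"].to_numpy()), ap_n)

    if compartment == "soil_pore_co2":
        if flux_model is None:
            raise ValueError("soil_pore_co2 excess requires a flux_model "
                             "(modelled CO2 efflux, mg C m-2 h-1)")
        flux = np.asarray(flux_model(t), dtype=float)
        values = excess_released(e, flux)
        kind = "rate"
    else:
        pools = sub.dropna(subset=["biomass_g_m2", "carbon_pct"])
        if pools.empty:
            raise ValueError(f"no biomass/%C observations to build a C pool "
                             f"for {compartment!r} in {mesocosm_id!r}")
        pt = pools["time_d"].to_numpy(dtype=float)
        pv = carbon_pool(pools["biomass_g_m2"].to_numpy(),
                         pools["carbon_pct"].to_numpy())
        pv = np.atleast_1d(pv)
        # nearest-in-time pool, no interpolation
        nearest = np.abs(t[:, None] - pt[None, :]).argmin(axis=1)
        values = excess_allocated(e, pv[nearest])
        kind = "pool"

    return ExcessSeries(compartment, mesocosm_id, t, np.atleast_1d(values), kind,
                        meta={"baseline_atom_percent": ap_n})
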
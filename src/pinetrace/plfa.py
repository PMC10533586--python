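"""Phospholipid fatty acid (PLFA) biomarker analysis.

PLFAs are membrane lipids of living soil microbes; individual fatty acids
act as biomarkers for microbial groups (e.g. 18:2w6,9 for fungi, 10Me-
branched acids for Actinobacteriota). This module classifies compounds,
aggregates group totals and community ratios (fungal:bacterial,
gram+:gram-), converts concentrations to areal PLFA-carbon pools for
tracer accounting, computes per-compound and per-group 13C excess, and
provides correspondence analysis of relative-abundance matrices.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import isotope
from .isotope import ExcessSeries

__all__ = [
    "BIOMARKER_GROUPS", "normalize_name", "classify_plfa", "GroupSummary",
    "group_summary", "carbon_fraction", "plfa_c_pool", "plfa_excess",
    "CAResult", "correspondence_analysis",
]

#: Biomarker assignments, keyed by normalized compound name.
BIOMARKER_GROUPS = {
    "general_bacteria": ("14:0", "15:0", "16:0", "17:0", "18:0", "20:0"),
    "gram_positive": ("i15:0", "a15:0", "i16:0", "i17:0", "a17:0"),
    "gram_negative": ("16:1ω7", "16:1ω5", "cy17:0", "18:1ω7", "cy19:0"),
    "actinobacteriota": ("10me16:0", "10me17:0", "10me18:0"),
    "fungi": ("18:2ω6,9",),
}

BACTERIAL_GROUPS = ("general_bacteria", "gram_positive", "gram_negative")

_GROUP_OF = {name: grp for grp, names in BIOMARKER_GROUPS.items() for name in names}


def normalize_name(name: str) -> str:
    """Canonical fatty-acid nomenclature: 'w' -> omega, strip a leading 'C'
    before digits (C16:0 == 16:0), case-insensitive."""
    s = str(name).strip().lower().replace("w", "ω")
    s = re.sub(r"^c(?=\d)", "", s)
    return s


def classify_plfa(name: str) -> str:
    """Microbial group of a fatty-acid biomarker.

    Deterministic from the name; unknown compounds map to ``unassigned``
    (never dropped silently).
    """
    if not str(name).strip():
        raise ValueError("empty PLFA name")
    return _GROUP_OF.get(normalize_name(name), "unassigned")


@dataclass
class GroupSummary:
    """Concentration totals per microbial group plus community ratios."""

    totals: dict                 # group -> ug g-1 dw soil
    fb_ratio: float              # fungi / (general + gram+ + gram-)
    gp_gn_ratio: float
    total_bacteria: float
    total_all: float             # every compound incl. actino/fungi/unassigned


def group_summary(profile: pd.DataFrame) -> GroupSummary:
    """Aggregate a profile (columns ``compound``, ``conc_ug_gdw``).

    The fungal:bacterial ratio divides the fungal marker by the sum of all
    bacterial biomarkers (general + gram-positive + gram-negative); a zero
    bacterial total makes the ratio undefined and is flagged.
    """
    df = profile.copy()
    if df["conc_ug_gdw"].lt(0).any():
        raise ValueError("PLFA concentrations must be >= 0")
    names = df["compound"].map(normalize_name)
    if names.duplicated().any():
        dup = names[names.duplicated()].tolist()
        raise ValueError(f"duplicate compounds in profile: {dup}")
    df["group"] = df["compound"].map(classify_plfa)
    totals = df.groupby("group")["conc_ug_gdw"].sum().to_dict()
    for g in (*BIOMARKER_GROUPS, "unassigned"):
        totals.setdefault(g, 0.0)
    bact = sum(totals[g] for g in BACTERIAL_GROUPS)
    if bact <= 0:
        warnings.warn("zero bacterial PLFA total; F:B ratio undefined",
                      stacklevel=2)
        fb = np.nan
    else:
        fb = totals["fungi"] / bact
    gp_gn = (totals["gram_positive"] / totals["gram_negative"]
             if totals["gram_negative"] > 0 else np.nan)
    return GroupSummary(totals=totals, fb_ratio=float(fb),
                        gp_gn_ratio=float(gp_gn), total_bacteria=float(bact),
                        total_all=float(df["conc_ug_gdw"].sum()))


_NAME_RE = re.compile(r"^(?P<prefix>10me|cy|i|a)?(?P<chain>\d+):(?P<unsat>\d+)")

_M_C, _M_H, _M_O = 12.011, 1.008, 15.999


def carbon_fraction(name: str) -> float:
    """Carbon mass fraction of a free fatty acid, parsed from nomenclature.

    Chain length and unsaturation give the molecular formula
    C_n H_(2n - 2*double_bonds - 2*rings) O2; iso/anteiso branches are part
    of the stated chain length, a 10-methyl branch adds one carbon, and a
    cyclopropane ring counts as one ring.
    """
    m = _NAME_RE.match(normalize_name(name))
    if not m:
        raise ValueError(f"cannot parse fatty-acid name {name!r}")
    n = int(m.group("chain"))
    unsat = int(m.group("unsat"))
    rings = 0
    if m.group("prefix") == "10me":
        n += 1
    elif m.group("prefix") == "cy":
        rings = 1
    h = 2 * n - 2 * unsat - 2 * rings
    mass = n * _M_C + h * _M_H + 2 * _M_O
    return n * _M_C / mass


def plfa_c_pool(conc_ug_gdw, soil_dry_mass_areal_kg_m2, carbon_frac=None,
                compound=None):
    """Areal PLFA-carbon pool, mg C m-2.

    ug g-1 dry soil x kg soil m-2 gives mg PLFA m-2; multiplied by the
    compound's carbon mass fraction (from its molecular formula unless
    overridden) to give mg PLFA-C m-2.
    """
    if carbon_frac is None:
        if compound is None:
            raise ValueError("give either carbon_frac or a compound name")
        carbon_frac = carbon_fraction(compound)
    conc = np.asarray(conc_ug_gdw, dtype=float)
    if np.any(conc < 0) or soil_dry_mass_areal_kg_m2 < 0 or carbon_frac < 0:
        raise ValueError("inputs must be >= 0")
    pool = conc * soil_dry_mass_areal_kg_m2 * carbon_frac
    return pool if pool.ndim else float(pool)


def plfa_profiles(table) -> pd.DataFrame:
    """Long PLFA table from a campaign: one row per compound x time.

    PLFA measurements are stored with compartment ``plfa:<compound>``; the
    concentration travels in ``plfa_ug_gdw``.
    """
    df = table.measurements
    sub = df[df["compartment"].str.startswith("plfa:")].copy()
    sub["compound"] = sub["compartment"].str.slice(len("plfa:"))
    sub = sub.rename(columns={"plfa_ug_gdw": "conc_ug_gdw"})
    return sub[["mesocosm_id", "treatment", "time_d", "compound",
                "conc_ug_gdw", "delta13c_permil"]]


def plfa_excess(table, mesocosm_id, carbon_frac_override=None):
    """Per-compound and per-group 13C excess series for one mesocosm.

    Each compound uses its own delta13C and its own concentration-derived
    carbon pool (no pooling of delta across compounds); the background is
    the compound's own pre-label atom%. Compounds lacking a pre-label
    baseline are excluded with a warning. Group series are sums of member
    compounds over the common sampling times.

    Returns
    -------
    (dict[str, ExcessSeries], dict[str, ExcessSeries])
        Per-compound and per-group series (mg 13C m-2).
    """
    prof = plfa_profiles(table)
    prof = prof[prof["mesocosm_id"] == mesocosm_id]
    if prof.empty:
        raise ValueError(f"no PLFA measurements for mesocosm {mesocosm_id!r}")
    soil_mass = table.mesocosms[mesocosm_id].soil_dry_mass_areal_kg_m2
    overrides = carbon_frac_override or {}

    per_compound = {}
    for compound, grp in prof.groupby("compound"):
        grp = grp.sort_values("time_d")
        pre = grp[(grp["time_d"] < 0) & grp["delta13c_permil"].notna()]
        if pre.empty:
            warnings.warn(f"PLFA {compound!r}: no pre-label baseline; "
                          "excluded from excess computation", stacklevel=2)
            continue
        ap_n = float(np.mean(isotope.delta_to_atom_percent(
            pre["delta13c_permil"].to_numpy())))
        grp = grp.dropna(subset=["delta13c_permil", "conc_ug_gdw"])
        e = isotope.enrichment(
            isotope.delta_to_atom_percent(grp["delta13c_permil"].to_numpy()), ap_n)
        cf = overrides.get(normalize_name(compound))
        pool = plfa_c_pool(grp["conc_ug_gdw"].to_numpy(), soil_mass,
                           carbon_frac=cf, compound=None if cf else compound)
        per_compound[compound] = ExcessSeries(
            f"plfa:{compound}", mesocosm_id, grp["time_d"].to_numpy(dtype=float),
            isotope.excess_allocated(e, pool), "pool",
            meta={"group": classify_plfa(compound)})

    per_group = {}
    for grp_name in BIOMARKER_GROUPS:
        members = [s for s in per_compound.values()
                   if s.meta["group"] == grp_name]
        if not members:
            continue
        times = members[0].times
        if not all(np.array_equal(s.times, times) for s in members):
            common = sorted(set.intersection(*(set(s.times) for s in members)))
            times = np.asarray(common)
            members = [ExcessSeries(s.compartment, s.mesocosm_id, times,
                                    s.values[np.isin(s.times, times)], "pool")
                       for s in members]
        total = np.sum([s.values for s in members], axis=0)
        per_group[grp_name] = ExcessSeries(f"plfa_group:{grp_name}",
                                           mesocosm_id, times, total, "pool")
    return per_compound, per_group


@dataclass
class CAResult:
    """Correspondence analysis of a non-negative contingency-style matrix.

    Coordinates are principal coordinates (scaled by the singular values);
    dimension inertias are the squared singular values of the standardized
    residual matrix and sum to chi-square / grand total.
    """

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    inertia: np.ndarray
    total_inertia: float
    grand_total: float

    @property
    def chi2(self) -> float:
        return self.total_inertia * self.grand_total

    @property
    def inertia_share(self) -> np.ndarray:
        return self.inertia / self.total_inertia

    def summary(self) -> str:
        lines = ["Correspondence analysis",
                 f"  total inertia (chi2/n): {self.total_inertia:.6g}"]
        for i, (v, s) in enumerate(zip(self.inertia, self.inertia_share), 1):
            lines.append(f"  dim {i}: inertia {v:.6g} ({100 * s:.1f}%)")
        return "\n".join(lines)


def correspondence_analysis(matrix: pd.DataFrame, tol: float = 1e-12) -> CAResult:
    """Standard CA by SVD of the standardized chi-square residuals.

    With correspondence matrix P = N / n, row/column margins r and c, the
    residual matrix S = D_r^-1/2 (P - r c^T) D_c^-1/2 is decomposed as
    U Sigma V^T; principal coordinates are F = D_r^-1/2 U Sigma (rows) and
    G = D_c^-1/2 V Sigma (columns). Dimensions are ordered by decreasing
    inertia (= squared singular value).
    """
    df = pd.DataFrame(matrix).astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("CA requires a non-negative matrix")
    if (df.sum(axis=1) <= 0).any() or (df.sum(axis=0) <= 0).any():
        raise ValueError("CA matrix must not contain all-zero rows or columns")
    n = float(df.to_numpy().sum())
    P = df.to_numpy() / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > tol * max(sv[0], 1.0) if sv.size else np.zeros(0, bool)
    if not keep.any():
        raise ValueError("degenerate matrix: all residual structure is zero "
                         "(rows and columns are independent)")
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    dims = [f"dim{i + 1}" for i in range(sv.size)]
    F = (U * sv) / np.sqrt(r)[:, None]
    G = (Vt.T * sv) / np.sqrt(c)[:, None]
    return CAResult(
        row_coords=pd.DataFrame(F, index=df.index, columns=dims),
        col_coords=pd.DataFrame(G, index=df.columns, columns=dims),
        inertia=sv ** 2, total_inertia=float(np.sum(sv ** 2)), grand_total=n)


def relative_abundance_matrix(table, times=None) -> pd.DataFrame:
    """Treatment x compound mean relative-abundance matrix for CA.

    Per profile (mesocosm x time) concentrations are converted to relative
    abundances, then averaged within treatment across mesocosms and all
    post-label sampling times (or the given subset).
    """
    prof = plfa_profiles(table)
    prof = prof[prof["time_d"] >= 0] if times is None else \
        prof[prof["time_d"].isin(times)]
    wide = prof.pivot_table(index=["treatment", "mesocosm_id", "time_d"],
                            columns="compound", values="conc_ug_gdw")
    rel = wide.div(wide.sum(axis=1), axis=0)
    return rel.groupby(level="treatment").mean()
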
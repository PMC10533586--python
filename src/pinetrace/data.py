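"""Data model and file I/O for pulse-labelling campaigns.

The canonical interchange format is a long (tidy) CSV with one observation
per row and the column contract::

    mesocosm_id, treatment, compartment, time_d, delta13c_permil,
    co2_ppm, carbon_pct, biomass_g_m2, plfa_ug_gdw

Times are days since the end of the 45-min labelling window; pre-label
baselines carry negative times. Missing observations are empty cells
(explicit nulls), never zeros. Mesocosm metadata and the continuous
environment record travel in sidecar CSVs next to the measurement file
(``<stem>.mesocosms.csv``, ``<stem>.environment.csv``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("pinetrace")

TREATMENTS = ("control", "intermediate", "severe")

#: Column contract of the long measurement CSV.
MEASUREMENT_COLUMNS = [
    "mesocosm_id", "treatment", "compartment", "time_d", "delta13c_permil",
    "co2_ppm", "carbon_pct", "biomass_g_m2", "plfa_ug_gdw",
]

ENVIRONMENT_COLUMNS = ["mesocosm_id", "time_d", "soil_temp_c", "vwc_pct"]

#: Ground area of one mesocosm pot, m2.
DEFAULT_GROUND_AREA_M2 = 0.37


class SchemaError(ValueError):
    """Input file does not match the expected column contract."""


class ValidationError(ValueError):
    """One or more rows violate a physical invariant; rows are listed."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid rows:\n" + "\n".join(self.problems))


@dataclass
class Mesocosm:
    """One potted tree-soil system (the experimental unit)."""

    id: str
    treatment: str
    tree_height_cm: float
    ground_area_m2: float = DEFAULT_GROUND_AREA_M2
    soil_dry_mass_areal_kg_m2: float = 283.8  # 105 kg soil (0-20 cm) / 0.37 m2

    def __post_init__(self):
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if not self.tree_height_cm > 0:
            raise ValueError("tree height must be positive")
        if not self.ground_area_m2 > 0:
            raise ValueError("ground area must be positive")


@dataclass
class CampaignTable:
    """A full campaign: mesocosm metadata + measurements (+ environment)."""

    mesocosms: dict
    measurements: pd.DataFrame
    environment: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=ENVIRONMENT_COLUMNS))

    def __post_init__(self):
        self.validate()

    def validate(self):
        df = self.measurements
        missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"measurement table lacks columns {missing}")
        problems = []
        known = set(self.mesocosms)
        for idx, row in df[~df["mesocosm_id"].isin(known)].iterrows():
            problems.append(f"row {idx}: unknown mesocosm_id {row['mesocosm_id']!r}")
        bad_delta = df["delta13c_permil"].notna() & (df["delta13c_permil"] < -1000)
        for idx in df.index[bad_delta]:
            problems.append(f"row {idx}: delta13c_permil < -1000 permil")
        bad_ppm = df["co2_ppm"].notna() & (df["co2_ppm"] < 0)
        for idx in df.index[bad_ppm]:
            problems.append(f"row {idx}: negative co2_ppm")
        bad_cpct = df["carbon_pct"].notna() & ~df["carbon_pct"].between(0, 100)
        for idx in df.index[bad_cpct]:
            problems.append(f"row {idx}: carbon_pct outside [0, 100]")
        if not self.environment.empty:
            bad_vwc = self.environment["vwc_pct"].notna() & \
                ~self.environment["vwc_pct"].between(0, 100)
            for idx in self.environment.index[bad_vwc]:
                problems.append(f"environment row {idx}: vwc_pct outside [0, 100]")
        if problems:
            raise ValidationError(problems)

    @property
    def treatment_of(self):
        return {mid: m.treatment for mid, m in self.mesocosms.items()}

    def mesocosm_ids(self, treatment=None):
        if treatment is None:
            return list(self.mesocosms)
        return [mid for mid, m in self.mesocosms.items() if m.treatment == treatment]


def _sidecar_paths(path):
    path = Path(path)
    stem = path.with_suffix("")
    return Path(f"{stem}.mesocosms.csv"), Path(f"{stem}.environment.csv")


def write_campaign(table: CampaignTable, path) -> Path:
    """Write a campaign as long CSV plus metadata/environment sidecars.

    Values are printed at full precision so that ``read_campaign`` restores
    the table bit-identically.
    """
    path = Path(path)
    table.measurements.to_csv(path, index=False, float_format="%.17g")
    meso_path, env_path = _sidecar_paths(path)
    meso = pd.DataFrame(
        [{"mesocosm_id": m.id, "treatment": m.treatment,
          "tree_height_cm": m.tree_height_cm,
          "ground_area_m2": m.ground_area_m2,
          "soil_dry_mass_areal_kg_m2": m.soil_dry_mass_areal_kg_m2}
         for m in table.mesocosms.values()])
    meso.to_csv(meso_path, index=False, float_format="%.17g")
    if not table.environment.empty:
        table.environment.to_csv(env_path, index=False, float_format="%.17g")
    log.info("wrote campaign to %s (%d measurement rows)", path,
             len(table.measurements))
    return path


def read_campaign(path) -> CampaignTable:
    """Read a campaign written by :func:`write_campaign`.

    Raises :class:`SchemaError` for missing columns, and a parse error
    naming the offending row for non-numeric values; rows violating
    physical invariants are rejected with row-level diagnostics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in ("time_d", "delta13c_permil", "co2_ppm", "carbon_pct",
                "biomass_g_m2", "plfa_ug_gdw"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()].tolist()
            raise SchemaError(f"{path}: non-numeric {col} in rows {bad}")

    meso_path, env_path = _sidecar_paths(path)
    if meso_path.exists():
        meso_df = pd.read_csv(meso_path, float_precision="round_trip")
        mesocosms = {
            str(r.mesocosm_id): Mesocosm(
                id=str(r.mesocosm_id), treatment=r.treatment,
                tree_height_cm=r.tree_height_cm,
                ground_area_m2=r.ground_area_m2,
                soil_dry_mass_areal_kg_m2=r.soil_dry_mass_areal_kg_m2)
            for r in meso_df.itertuples()}
    else:
        # minimal metadata recovered from the measurement table itself
        mesocosms = {
            str(mid): Mesocosm(id=str(mid), treatment=trt, tree_height_cm=72.0)
            for (mid, trt) in df[["mesocosm_id", "treatment"]]
            .drop_duplicates().itertuples(index=False)}
    df["mesocosm_id"] = df["mesocosm_id"].astype(str)
    env = (pd.read_csv(env_path, float_precision="round_trip") if env_path.exists()
           else pd.DataFrame(columns=ENVIRONMENT_COLUMNS))
    if not env.empty:
        env["mesocosm_id"] = env["mesocosm_id"].astype(str)
    return CampaignTable(mesocosms=mesocosms, measurements=df, environment=env)


def import_xlsx(path, sheet, column_map, treatment_of=None) -> pd.DataFrame:
    """Import one sheet of a supplementary spreadsheet into the long contract.

    ``column_map`` maps contract column names to spreadsheet column names;
    unmapped contract columns are filled with nulls. This keeps spreadsheet
    dialects out of the core pipeline, which only ever sees the tidy CSV
    layout.
    """
    raw = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    out = pd.DataFrame(index=raw.index, columns=MEASUREMENT_COLUMNS, dtype=object)
    for contract_col, sheet_col in column_map.items():
        if contract_col not in MEASUREMENT_COLUMNS:
            raise SchemaError(f"unknown contract column {contract_col!r}")
        if sheet_col not in raw.columns:
            raise SchemaError(f"{path}:{sheet}: missing column {sheet_col!r}")
        out[contract_col] = raw[sheet_col].to_numpy()
    if treatment_of and "treatment" not in column_map:
        out["treatment"] = out["mesocosm_id"].astype(str).map(treatment_of)
    for col in ("time_d", "delta13c_permil", "co2_ppm", "carbon_pct",
                "biomass_g_m2", "plfa_ug_gdw"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    return out


def summarize_by_treatment(values, treatment_of) -> pd.DataFrame:
    """Per-treatment mean and standard error of per-mesocosm scalars.

    Parameters
    ----------
    values : mapping or pandas.Series
        Scalar per mesocosm_id.
    treatment_of : mapping
        mesocosm_id -> treatment.

    Returns
    -------
    pandas.DataFrame indexed by treatment with columns mean, se, n.
    SE is the sample standard deviation over sqrt(n); single-mesocosm
    groups get se = NaN with a warning; treatments present in the mapping
    but with no values are flagged with n = 0 rather than dropped.
    """
    s = pd.Series(dict(values), dtype=float)
    trt = pd.Series({k: treatment_of[k] for k in s.index})
    rows = {}
    for t in dict.fromkeys(treatment_of.values()):
        vals = s[trt == t].dropna()
        n = len(vals)
        if n == 0:
            warnings.warn(f"treatment {t!r} has no values", stacklevel=2)
            rows[t] = (np.nan, np.nan, 0)
        elif n == 1:
            warnings.warn(f"treatment {t!r} has a single mesocosm; "
                          "SE undefined", stacklevel=2)
            rows[t] = (float(vals.iloc[0]), np.nan, 1)
        else:
            rows[t] = (float(vals.mean()),
                       float(vals.std(ddof=1) / np.sqrt(n)), n)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["mean", "se", "n"])
    out.index.name = "treatment"
    return out
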
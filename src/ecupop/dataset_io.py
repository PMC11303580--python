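"""NONMEM-style event-record datasets.

The analysis dataset is a long-format table of dose and observation events,
one row per event, with the usual pharmacometric column dialect:

====== =====================================================================
ID     subject identifier
TIME   hours since first dose (weeks convert as 168*w)
EVID   1 for dose events, 0 for observations
AMT    dose amount (mg), dose rows only
RATE   infusion rate (mg/h), dose rows only
DV     observation value (ug/mL PK, % TCA, U/L LDH); missing as "." / empty
DVID   observation type: 1 PK, 2 PD (TCA), 3 LDH
MDV    1 when the DV is missing / excluded from the likelihood
BLQ    1 when a PK DV lies below the lower limit of quantification
WT     body weight (kg)
POP    population: "healthy" or "PNH"
TRT    treatment label: "SB12", "EU-ECU" or "US-ECU"
PER    treatment period (1 or 2; phase III cross-over)
SEQ    treatment sequence ("I": SB12 then ECU, "II": ECU then SB12)
STUDY  "phase1" or "phase3"
SCREEN 1 for screening (pre-study) laboratory records used only for
       baseline imputation
====== =====================================================================

Missingness follows the analysis rules for these trials: PK observations
below the 0.8 ug/mL LLOQ and PK observations drawn before a subject's first
dose are flagged missing and excluded from estimation (M1 handling); a
missing day-1 LDH baseline is imputed from the screening record.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CORE_COLUMNS", "DVID_PK", "DVID_PD", "DVID_LDH",
    "StudyDataset", "read_dataset", "write_dataset", "apply_missingness_rules",
]

DVID_PK, DVID_PD, DVID_LDH = 1, 2, 3

CORE_COLUMNS = ["ID", "TIME", "EVID", "AMT", "RATE", "DV", "DVID", "MDV",
                "BLQ", "WT", "POP", "TRT", "PER", "SEQ", "STUDY", "SCREEN"]

_NUMERIC = ["TIME", "EVID", "AMT", "RATE", "DV", "DVID", "MDV", "BLQ", "WT",
            "PER", "SCREEN"]
_DEFAULTS = {"AMT": 0.0, "RATE": 0.0, "DV": np.nan, "DVID": 0, "MDV": 0,
             "BLQ": 0, "WT": np.nan, "POP": "healthy", "TRT": "SB12",
             "PER": 1, "SEQ": "I", "STUDY": "phase1", "SCREEN": 0}


class SchemaError(ValueError):
    """Raised when a dataset file does not match the expected schema."""


@dataclass
class StudyDataset:
    """An ordered collection of dose/observation events plus metadata."""

    df: pd.DataFrame
    lloq_pk: float = 0.8           # ug/mL
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = _normalize(self.df)
        _validate(self.df)

    # -- convenience accessors ---------------------------------------------
    @property
    def subjects(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return int(self.df["ID"].nunique())

    def doses(self, subject=None) -> pd.DataFrame:
        d = self.df[self.df["EVID"] == 1]
        return d if subject is None else d[d["ID"] == subject]

    def observations(self, dvid: int | None = None,
                     include_missing: bool = False) -> pd.DataFrame:
        o = self.df[self.df["EVID"] == 0]
        if dvid is not None:
            o = o[o["DVID"] == dvid]
        if not include_missing:
            o = o[o["MDV"] == 0]
        return o

    def equals(self, other: "StudyDataset") -> bool:
        if abs(self.lloq_pk - other.lloq_pk) > 0:
            return False
        a, b = self.df.reset_index(drop=True), other.df.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if c in _NUMERIC:
                av, bv = a[c].to_numpy(float), b[c].to_numpy(float)
                if not np.array_equal(av, bv, equal_nan=True):
                    return False
            elif not a[c].astype(str).equals(b[c].astype(str)):
                return False
        return True

    def copy(self) -> "StudyDataset":
        return StudyDataset(self.df.copy(), self.lloq_pk, dict(self.metadata))


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Fill defaults, coerce dtypes and apply the canonical event ordering."""
    df = df.copy()
    if "ID" not in df.columns or "TIME" not in df.columns:
        raise SchemaError("dataset requires at least ID and TIME columns")
    if "EVID" not in df.columns:
        df["EVID"] = 0
    for col, default in _DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    for col in _NUMERIC:
        try:
            df[col] = pd.to_numeric(df[col].replace({".": np.nan, "": np.nan}))
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(
                df[col].replace({".": np.nan, "": np.nan}), errors="coerce"
            ).isna() & df[col].notna()]
            row = int(bad[0]) if len(bad) else -1
            raise SchemaError(f"non-numeric value in column {col} at row {row}") from exc
    df["AMT"] = df["AMT"].fillna(0.0)
    df["RATE"] = df["RATE"].fillna(0.0)
    df["MDV"] = np.where(df["DV"].isna() & (df["EVID"] == 0), 1, df["MDV"])
    df["MDV"] = df["MDV"].fillna(0).astype(int)
    for col in ("EVID", "DVID", "BLQ", "PER", "SCREEN"):
        df[col] = df[col].fillna(0).astype(int)
    # stable sort: subjects keep first-appearance order, events by time with
    # dose rows before observations at identical times
    first_seen = {s: i for i, s in enumerate(df["ID"].unique())}
    order = df.assign(_s=df["ID"].map(first_seen), _e=-df["EVID"]) \
              .sort_values(["_s", "TIME", "_e"], kind="stable").index
    df = df.loc[order].reset_index(drop=True)
    extras = [c for c in df.columns if c not in CORE_COLUMNS]
    return df[CORE_COLUMNS + sorted(extras)]


def _validate(df: pd.DataFrame) -> None:
    if (df["TIME"] < 0).any():
        raise SchemaError("negative event times")
    dose = df[df["EVID"] == 1]
    if (dose["AMT"] <= 0).any() or (dose["RATE"] <= 0).any():
        raise SchemaError("dose events require positive AMT and RATE")
    obs = df[df["EVID"] == 0]
    if not obs["DVID"].isin([DVID_PK, DVID_PD, DVID_LDH]).all():
        raise SchemaError("observations must carry DVID in {1, 2, 3}")
    wt = df["WT"].dropna()
    if (wt <= 0).any():
        raise SchemaError("weights must be positive")
    pops = df.groupby("ID", sort=False)["POP"].nunique()
    if (pops > 1).any():
        raise SchemaError("population must be constant within subject")
    key = df[df["EVID"] == 0].groupby(
        ["ID", "TIME", "DVID", "SCREEN"], sort=False).size()
    if (key > 1).any():
        raise SchemaError("duplicate (subject, time, observation type) events")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_dataset(path, schema: dict | None = None, lloq_pk: float = 0.8) -> StudyDataset:
    """Read a NONMEM-style CSV into a :class:`StudyDataset`.

    ``schema`` optionally maps file column names to the canonical dialect
    (e.g. ``{"SUBJ": "ID", "CONC": "DV"}``).  Missing DV cells ("." or
    empty) become missing-flagged observations, and PK observations that
    precede a subject's first dose are flagged missing.
    """
    df = pd.read_csv(path, na_values=["."], keep_default_na=True,
                     float_precision="round_trip")
    if schema:
        df = df.rename(columns=schema)
    missing = {"ID", "TIME"} - set(df.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {sorted(missing)}")
    ds = StudyDataset(df, lloq_pk=lloq_pk)
    ds.df = _flag_predose_pk(ds.df)
    return ds


def write_dataset(ds: StudyDataset, path) -> None:
    """Write a dataset as canonical CSV (deterministic order; DV "." when missing)."""
    out = ds.df.copy()
    out["DV"] = out["DV"].map(lambda v: "." if pd.isna(v) else repr(float(v)))
    out["WT"] = out["WT"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    out.to_csv(buf, index=False, lineterminator="\n")
    path.write_text(buf.getvalue())


def _flag_predose_pk(df: pd.DataFrame) -> pd.DataFrame:
    """Flag PK observations before a subject's first dose as missing."""
    df = df.copy()
    first_dose = df[df["EVID"] == 1].groupby("ID")["TIME"].min()
    fd = df["ID"].map(first_dose)
    # a PK sample at exactly the first dose start is the pre-dose baseline
    pre = (df["EVID"] == 0) & (df["DVID"] == DVID_PK) & (fd.isna() | (df["TIME"] <= fd))
    df.loc[pre, "MDV"] = 1
    return df


def apply_missingness_rules(ds: StudyDataset) -> tuple[StudyDataset, float]:
    """Apply the analysis missingness rules; return (dataset, PK BLQ fraction).

    * PK observations with DV below the LLOQ are flagged BLQ and missing
      (M1: excluded from the likelihood, value retained in the table).
    * PK observations before the subject's first dose are flagged missing.
    * A missing day-1 LDH baseline is imputed from the subject's screening
      LDH record, when one exists.

    Idempotent, and the BLQ fraction (share of all PK observation records
    whose value lies below the LLOQ) is a deterministic function of the
    dataset and the LLOQ.
    """
    df = ds.df.copy()
    pk = (df["EVID"] == 0) & (df["DVID"] == DVID_PK) & (df["SCREEN"] == 0)
    blq = pk & (df["DV"].fillna(np.inf) < ds.lloq_pk)
    df.loc[pk, "BLQ"] = 0
    df.loc[blq, "BLQ"] = 1
    df.loc[blq, "MDV"] = 1
    df = _flag_predose_pk(df)

    # LDH baseline imputation from screening
    ldh = (df["EVID"] == 0) & (df["DVID"] == DVID_LDH)
    for sid, sub in df[ldh].groupby("ID", sort=False):
        base = sub[(sub["SCREEN"] == 0) & (sub["TIME"] == 0.0)]
        screen = sub[(sub["SCREEN"] == 1) & sub["DV"].notna()]
        has_base_value = bool(len(base)) and base["DV"].notna().any() \
            and (base.loc[base["DV"].notna(), "MDV"] == 0).any()
        if has_base_value or not len(screen):
            continue
        value = float(screen.iloc[0]["DV"])
        if len(base):
            df.loc[base.index[0], ["DV", "MDV"]] = [value, 0]
        else:  # promote the screening record to a day-1 baseline
            idx = screen.index[0]
            df.loc[idx, ["TIME", "SCREEN", "MDV"]] = [0.0, 0, 0]

    n_pk = int(pk.sum())
    blq_fraction = float(blq.sum() / n_pk) if n_pk else 0.0
    out = StudyDataset(df, ds.lloq_pk, dict(ds.metadata))
    out.metadata["blq_fraction_pk"] = blq_fraction
    return out, blq_fraction
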
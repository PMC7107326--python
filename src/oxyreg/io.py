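"""Reading and writing respirometry traces, rate profiles and result tables.

All on-disk formats are delimited text (CSV by default). Traces come in two
dialects: *long* (one row per sample: trace_id, time, oxygen) and *wide*
(one time column plus one oxygen column per chamber). Metadata may live in
extra columns of the trace table or in a sidecar table keyed by trace_id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("oxyreg")

__all__ = [
    "TraceMetadata",
    "RespirometryTrace",
    "RateProfile",
    "FormatError",
    "ValidationError",
    "read_trace_table",
    "read_rate_profiles",
    "write_rate_profiles",
    "write_results",
]


class FormatError(ValueError):
    """A required column or structural feature of an input file is missing."""


class ValidationError(ValueError):
    """Input parsed but violates an invariant (e.g. non-monotone time)."""


@dataclass(frozen=True)
class TraceMetadata:
    """Per-chamber metadata for one respirometry measurement.

    Weights are in mg; ``weight_basis`` says whether ``weight_mg`` is wet or
    dry mass (dry mass must be converted before rates become mass-specific).
    Blank chambers (``is_blank``) hold no animal and measure background
    (bacterial) oxygen demand.
    """

    trace_id: str
    species: str = ""
    temperature_C: float = float("nan")
    chamber_volume_mL: float = float("nan")
    weight_mg: float = float("nan")
    weight_basis: str = "wet"  # "wet" | "dry"
    is_blank: bool = False
    sampling_interval_s: float = float("nan")
    salinity_psu: float = float("nan")

    def __post_init__(self):
        if self.weight_basis not in ("wet", "dry"):
            raise ValidationError(
                f"weight_basis must be 'wet' or 'dry', got {self.weight_basis!r}"
            )
        if np.isfinite(self.chamber_volume_mL) and self.chamber_volume_mL <= 0:
            raise ValidationError(f"{self.trace_id}: chamber_volume_mL must be > 0")
        if (
            not self.is_blank
            and np.isfinite(self.weight_mg)
            and self.weight_mg <= 0
        ):
            raise ValidationError(f"{self.trace_id}: weight_mg must be > 0")


@dataclass
class RespirometryTrace:
    """Raw dissolved-oxygen time series (% air saturation) for one chamber."""

    metadata: TraceMetadata
    time_s: np.ndarray
    do_pct_airsat: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.do_pct_airsat = np.asarray(self.do_pct_airsat, dtype=float)
        tid = self.metadata.trace_id
        if self.time_s.shape != self.do_pct_airsat.shape:
            raise ValidationError(f"{tid}: time and oxygen lengths differ")
        if self.time_s.size < 3:
            raise ValidationError(f"{tid}: trace needs at least 3 samples")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValidationError(f"{tid}: time must be strictly increasing")
        if np.any(self.do_pct_airsat < 0) or np.any(self.do_pct_airsat > 110):
            raise ValidationError(
                f"{tid}: oxygen outside [0, 110] %air saturation"
            )

    @property
    def trace_id(self) -> str:
        return self.metadata.trace_id

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass
class RateProfile:
    """Paired (oxygen, mass-specific rate) points for one individual.

    Rates are in mL O2 h^-1 g wet weight^-1; oxygen in % air saturation,
    stored in descending oxygen order (the direction of a closed-chamber run).
    """

    trace_id: str
    do_pct_airsat: np.ndarray
    rate_mlO2_h_gww: np.ndarray
    species: str = ""
    temperature_C: float = float("nan")
    qc_pass: bool = True
    qc_reason: str = ""

    def __post_init__(self):
        self.do_pct_airsat = np.asarray(self.do_pct_airsat, dtype=float)
        self.rate_mlO2_h_gww = np.asarray(self.rate_mlO2_h_gww, dtype=float)
        if self.do_pct_airsat.shape != self.rate_mlO2_h_gww.shape:
            raise ValidationError(f"{self.trace_id}: oxygen/rate lengths differ")
        if not np.all(np.isfinite(self.rate_mlO2_h_gww)):
            raise ValidationError(f"{self.trace_id}: non-finite rates")
        if np.any(self.do_pct_airsat < 0):
            raise ValidationError(f"{self.trace_id}: negative oxygen")
        order = np.argsort(-self.do_pct_airsat, kind="stable")
        self.do_pct_airsat = self.do_pct_airsat[order]
        self.rate_mlO2_h_gww = self.rate_mlO2_h_gww[order]

    def __len__(self) -> int:
        return int(self.do_pct_airsat.size)


_META_COLUMNS = {
    "species": str,
    "temperature_C": float,
    "chamber_volume_mL": float,
    "weight_mg": float,
    "weight_basis": str,
    "is_blank": bool,
    "sampling_interval_s": float,
    "salinity_psu": float,
}

DEFAULT_COLUMN_MAP = {"trace_id": "trace_id", "time": "time_s", "oxygen": "do_pct_airsat"}


def _read_table(path, sep=",", decimal=".") -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, decimal=decimal)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _metadata_from_row(trace_id: str, row: Mapping) -> TraceMetadata:
    kwargs = {}
    for name, typ in _META_COLUMNS.items():
        if name in row and pd.notna(row[name]):
            val = row[name]
            if typ is bool and not isinstance(val, (bool, np.bool_)):
                val = str(val).strip().lower() in ("1", "true", "yes")
            else:
                val = typ(val)
            kwargs[name] = val
    return TraceMetadata(trace_id=str(trace_id), **kwargs)


def _require_numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        raise ValidationError(
            f"{path}: non-numeric values in column {col!r} "
            f"(first offending value: {df[col][bad].iloc[0]!r})"
        )
    if vals.isna().any():
        raise ValidationError(f"{path}: missing values in column {col!r}")
    return vals.to_numpy(dtype=float)


def read_trace_table(
    path,
    dialect: str = "long",
    column_map: Mapping[str, str] | None = None,
    metadata_path=None,
    sep: str = ",",
    decimal: str = ".",
) -> list[RespirometryTrace]:
    """Read respirometry traces from a delimited-text table.

    Parameters
    ----------
    dialect : {"long", "wide"}
        *long*: columns (trace_id, time, oxygen), metadata either inline or in
        ``metadata_path``. *wide*: one time column, one oxygen column per
        chamber; chamber column names become trace ids.
    column_map : mapping
        Maps logical names ("trace_id", "time", "oxygen") to header names.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = _read_table(path, sep=sep, decimal=decimal)
    if df.empty:
        logger.warning("read_trace_table: %s is empty", path)
        return []

    meta_df = None
    if metadata_path is not None:
        meta_df = _read_table(metadata_path, sep=sep, decimal=decimal)
        if "trace_id" not in meta_df.columns:
            raise FormatError(f"{metadata_path}: metadata table lacks 'trace_id'")
        meta_df = meta_df.set_index(meta_df["trace_id"].astype(str))

    traces: list[RespirometryTrace] = []
    if dialect == "long":
        for logical in ("trace_id", "time", "oxygen"):
            if cmap[logical] not in df.columns:
                raise FormatError(
                    f"{path}: missing required column {cmap[logical]!r} ({logical})"
                )
        time = _require_numeric(df, cmap["time"], path)
        oxy = _require_numeric(df, cmap["oxygen"], path)
        work = df.copy()
        work["_t"] = time
        work["_o"] = oxy
        for tid, sub in work.groupby(work[cmap["trace_id"]].astype(str), sort=True):
            sub = sub.sort_values("_t")
            t = sub["_t"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"{path}: duplicated or non-increasing timestamps in trace {tid!r}"
                )
            row = sub.iloc[0]
            if meta_df is not None and str(tid) in meta_df.index:
                meta = _metadata_from_row(tid, meta_df.loc[str(tid)])
            else:
                meta = _metadata_from_row(tid, row)
            traces.append(RespirometryTrace(meta, t, sub["_o"].to_numpy()))
    elif dialect == "wide":
        tcol = cmap["time"]
        if tcol not in df.columns:
            raise FormatError(f"{path}: missing time column {tcol!r}")
        oxy_cols = [c for c in df.columns if c != tcol and c not in _META_COLUMNS]
        if not oxy_cols:
            raise FormatError(f"{path}: no oxygen columns beside {tcol!r}")
        t = _require_numeric(df, tcol, path)
        order = np.argsort(t, kind="stable")
        if np.any(np.diff(t[order]) <= 0):
            raise ValidationError(f"{path}: duplicated timestamps in wide table")
        for col in oxy_cols:
            oxy = _require_numeric(df, col, path)[order]
            if meta_df is not None and str(col) in meta_df.index:
                meta = _metadata_from_row(col, meta_df.loc[str(col)])
            else:
                meta = TraceMetadata(trace_id=str(col))
            traces.append(RespirometryTrace(meta, t[order], oxy))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return traces


def read_rate_profiles(path, sep: str = ",", decimal: str = ".") -> list[RateProfile]:
    """Read pre-derived rate-vs-oxygen profiles (one row per point).

    Required columns: trace_id, do_pct_airsat, rate_mlO2_h_gww; optional
    species, temperature_C. Profiles are returned ordered by descending oxygen.
    """
    df = _read_table(path, sep=sep, decimal=decimal)
    if df.empty:
        logger.warning("read_rate_profiles: %s is empty", path)
        return []
    for col in ("trace_id", "do_pct_airsat", "rate_mlO2_h_gww"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    oxy = _require_numeric(df, "do_pct_airsat", path)
    if np.any(oxy < 0):
        raise ValidationError(f"{path}: negative oxygen values")
    rate = _require_numeric(df, "rate_mlO2_h_gww", path)
    work = df.copy()
    work["_o"], work["_r"] = oxy, rate
    profiles = []
    for tid, sub in work.groupby(work["trace_id"].astype(str), sort=True):
        profiles.append(
            RateProfile(
                trace_id=str(tid),
                do_pct_airsat=sub["_o"].to_numpy(),
                rate_mlO2_h_gww=sub["_r"].to_numpy(),
                species=str(sub["species"].iloc[0]) if "species" in sub else "",
                temperature_C=float(sub["temperature_C"].iloc[0])
                if "temperature_C" in sub
                else float("nan"),
            )
        )
    return profiles


def write_rate_profiles(profiles: Iterable[RateProfile], path, sep: str = ",") -> None:
    """Write rate profiles in the long format that ``read_rate_profiles`` reads."""
    rows = []
    for p in profiles:
        for o, r in zip(p.do_pct_airsat, p.rate_mlO2_h_gww):
            rows.append(
                {
                    "trace_id": p.trace_id,
                    "species": p.species,
                    "temperature_C": p.temperature_C,
                    "do_pct_airsat": repr(float(o)),
                    "rate_mlO2_h_gww": repr(float(r)),
                }
            )
    pd.DataFrame(
        rows,
        columns=["trace_id", "species", "temperature_C", "do_pct_airsat", "rate_mlO2_h_gww"],
    ).to_csv(path, sep=sep, index=False)


def write_results(results: Sequence, path, sep: str = ",", allow_empty: bool = False) -> None:
    """Write RIResults or GroupSummary records as a delimited table.

    Numeric columns are serialized at full precision; a rounded (2-decimal)
    display column is appended for each of the headline numbers.
    """
    results = list(results)
    if not results and not allow_empty:
        raise ValueError("write_results: empty input (pass allow_empty=True to permit)")
    if not results:
        pd.DataFrame(columns=["trace_id"]).to_csv(path, sep=sep, index=False)
        return
    rows = [asdict(r) if hasattr(r, "__dataclass_fields__") else dict(r) for r in results]
    df = pd.DataFrame(rows)
    for col in ("ri", "ri_median", "ri_q1", "ri_q3"):
        if col in df.columns:
            df[f"{col}_2dp"] = df[col].round(2)
    float_cols = df.select_dtypes(include=[float]).columns
    df[float_cols] = df[float_cols].map(lambda v: repr(float(v)))
    df.to_csv(path, sep=sep, index=False)
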
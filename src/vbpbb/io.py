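"""CSV/YAML/JSON readers and writers for every pipeline artifact.

The method assumes a complete, strictly daily series, so the reader is
deliberately strict: calendar gaps, duplicate dates, missing or
non-numeric values are hard errors reported with their row numbers rather
than silently imputed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bootstrap import CIBand, band_to_frame
from .kzft import PCComponent
from .pipeline import ComponentPlan, VBPBBResult, summary_table
from .series import RegularSeries

__all__ = [
    "read_series",
    "write_series",
    "write_component",
    "write_band",
    "write_summary",
    "write_log",
    "read_plans",
    "write_ground_truth",
]


def read_series(
    path, date_column: str = "date", value_column: str = "value"
) -> RegularSeries:
    """Read a (date, value) CSV as a strictly daily complete series."""
    df = pd.read_csv(path)
    for col in (date_column, value_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    try:
        dates = pd.to_datetime(df[date_column], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable dates in {date_column!r}: {exc}") from exc
    values = pd.to_numeric(df[value_column], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(values.to_numpy(dtype=float)))
    if bad.size:
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(
            f"{path}: missing or non-numeric values at row(s) {rows}"
            + (" ..." if bad.size > 10 else "")
        )
    diffs = dates.diff().dropna()
    dup = np.flatnonzero((diffs == pd.Timedelta(0)).to_numpy())
    if dup.size:
        raise ValueError(f"{path}: duplicate date at row {dup[0] + 3}")
    gaps = np.flatnonzero((diffs != pd.Timedelta(days=1)).to_numpy())
    if gaps.size:
        i = int(gaps[0])
        raise ValueError(
            f"{path}: gap or disorder between rows {i + 2} and {i + 3} "
            f"({dates.iloc[i].date()} -> {dates.iloc[i + 1].date()})"
        )
    return RegularSeries(values.to_numpy(dtype=float), start=dates.iloc[0])


def write_series(x: RegularSeries, path) -> None:
    """Write a series as a (date, value) CSV (index column when unanchored)."""
    dates = x.dates()
    if dates is not None:
        col = dates.strftime("%Y-%m-%d")
    else:
        col = np.arange(len(x))
    pd.DataFrame({"date": col, "value": x.values}).to_csv(
        path, index=False, float_format="%.10g"
    )


def write_component(comp: PCComponent, path) -> None:
    """Filtered component as CSV: date (or index), value, valid flag."""
    x = comp.series
    dates = x.dates()
    col = dates.strftime("%Y-%m-%d") if dates is not None else np.arange(len(x))
    pd.DataFrame(
        {"date": col, "value": x.values, "valid": x.valid_mask.astype(int)}
    ).to_csv(path, index=False, float_format="%.10g")


def write_band(band: CIBand, path) -> None:
    band_to_frame(band).to_csv(path, index=False, float_format="%.10g")


def write_summary(results: dict[str, VBPBBResult], path) -> None:
    """Summary table (TSV): period, frequency, bound ranges, verdict."""
    if results:
        df = summary_table(results)
    else:
        df = pd.DataFrame(
            columns=[
                "period", "label", "frequency", "upper_min", "upper_max",
                "lower_min", "lower_max", "significant",
            ]
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_log(params: dict, path) -> None:
    """Plain-text run log: every parameter as one `key: value` line."""
    lines = [f"{k}: {params[k]}" for k in params]
    Path(path).write_text("\n".join(lines) + "\n")


def read_plans(path) -> list[ComponentPlan]:
    """Component plans from YAML: a list of {label, period, nu?, m?, k?}."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list):
        raise ValueError(f"{path}: expected a YAML list of plans")
    plans = []
    for entry in raw:
        plans.append(
            ComponentPlan(
                label=str(entry["label"]),
                p=int(entry["period"]),
                nu=entry.get("nu"),
                m=entry.get("m"),
                k=int(entry.get("k", 1)),
            )
        )
    return plans


def write_ground_truth(truth: dict, path) -> None:
    """JSON sidecar mapping each period to its periodic-mean vector."""
    def key(period):
        return str(int(period)) if float(period).is_integer() else str(period)

    payload = {key(period): np.asarray(v).tolist() for period, v in truth.items()}
    Path(path).write_text(json.dumps(payload, indent=1))
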
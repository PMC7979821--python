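"""CSV readers and writers for the pipeline's delimited-table interfaces.

All tables are comma-delimited UTF-8 with mandatory headers and units embedded
in the column names. Readers validate required columns, drop malformed rows
(non-numeric, out-of-range) with a logged count, and return plain DataFrames.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .hydrography import SurfaceInventory

logger = logging.getLogger(__name__)

CHEMISTRY_REQUIRED = ("site_id", "region", "pH", "alkalinity_ueq_L", "temp_C")
HYDRAULICS_REQUIRED = ("site_id", "velocity_m_s", "slope")
NETWORK_REQUIRED = ("segment_id", "downstream_id", "length_km", "region")


class SchemaError(ValueError):
    """An input table is missing required columns."""


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _drop_bad(df: pd.DataFrame, mask: pd.Series, path, reason: str) -> pd.DataFrame:
    n_bad = int((~mask).sum())
    if n_bad:
        logger.warning("%s: skipped %d malformed rows (%s)", path, n_bad, reason)
    return df[mask]


def read_chemistry_csv(path: str | Path) -> pd.DataFrame:
    """Gauge chemistry observations; malformed rows skipped with a logged count."""
    df = pd.read_csv(path)
    _require(df, CHEMISTRY_REQUIRED, path)
    for col in ("pH", "alkalinity_ueq_L", "temp_C"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df["pH"].between(0, 14, inclusive="neither")
        & (df["alkalinity_ueq_L"] >= 0)
        & df["temp_C"].between(-0.5, 45)
    )
    return _drop_bad(df, ok.fillna(False), path, "non-numeric or out-of-range chemistry")


def read_hydraulics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, HYDRAULICS_REQUIRED, path)
    for col in df.columns:
        if col not in ("site_id", "region"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (df["velocity_m_s"] >= 0) & df["slope"].between(0, 1, inclusive="left")
    return _drop_bad(df, ok.fillna(False), path, "non-numeric or out-of-range hydraulics")


def read_network_csv(path: str | Path) -> dict[str, str | None]:
    """Edge list as a segment -> downstream mapping (None for outlets)."""
    df = pd.read_csv(path, dtype={"segment_id": str, "downstream_id": str})
    _require(df, NETWORK_REQUIRED, path)
    return {
        r.segment_id: (r.downstream_id if isinstance(r.downstream_id, str) and r.downstream_id else None)
        for r in df.itertuples()
    }


def read_inventory_csv(path: str | Path, period: str = "", water_type: str = "stream") -> SurfaceInventory:
    df = pd.read_csv(path)
    if "stratum" in df.columns and water_type == "stream":
        try:
            df["stratum"] = pd.to_numeric(df["stratum"])
        except (ValueError, TypeError):
            pass  # size-class labels stay as strings
    return SurfaceInventory(df, period=period, water_type=water_type)


def read_flux_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_ice_free_csv(path: str | Path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path)
    _require(df, ("region", "season", "ice_free_days"), path)
    out: dict[str, dict[str, float]] = {}
    for r in df.itertuples():
        out.setdefault(r.region, {})[r.season] = float(r.ice_free_days)
    return out


def write_flux_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Flux tables get explicit unit-suffixed headers on the way out."""
    out = df.rename(
        columns={"mean_F": "mean_F_mmol_m2_d", "sd_F": "sd_F_mmol_m2_d", "area_m2": "area_m2"}
    )
    out.to_csv(path, index=False)
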
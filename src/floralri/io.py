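"""CSV readers and writers for the pipeline's tabular interfaces.

All tables are plain UTF-8 comma-separated files with a header row,
"." decimal separator and the sentinel ``NA`` for not-measured values.
Schema violations raise :class:`~floralri.errors.SchemaError` carrying
file, row and column context.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .phenology import PhenologySeries

__all__ = [
    "read_phenology",
    "read_morphology",
    "read_positions",
    "read_crosses",
    "read_seeds",
    "read_germination",
    "read_barriers",
    "write_table",
]

NA_VALUES = ["NA", ""]

PHENOLOGY_COLUMNS = ["species", "season", "date", "n_flowering", "n_sampled"]
MORPHOLOGY_COLUMNS = ["species", "plant_id", "flower_id", "corolla_length_mm",
                      "corolla_aperture_mm", "stamen_length_mm", "pistil_length_mm"]
POSITION_COLUMNS = ["species", "position_category"]
CROSS_COLUMNS = ["recipient", "donor", "flowers_pollinated", "fruits_set"]
SEED_COLUMNS = ["recipient", "donor", "fruit_id", "n_seeds"]
GERMINATION_COLUMNS = ["recipient", "donor", "replicate", "seeds_sown", "seeds_germinated"]
BARRIER_COLUMNS = ["recipient", "donor", "barrier", "strength"]


def _read(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=False)
    except FileNotFoundError:
        raise SchemaError("file not found", file=str(path)) from None
    except pd.errors.ParserError as exc:
        raise SchemaError(f"cannot parse CSV: {exc}", file=str(path)) from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing}", file=str(path))
    return df


def _int_column(df: pd.DataFrame, col: str, path: str, minimum: int = 0) -> None:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() | (vals != vals.round()) | (vals < minimum)
    if bad.any():
        raise SchemaError(
            f"expected integers >= {minimum}",
            file=path, row=int(bad.idxmax()) + 2, column=col,  # +2: header + 1-based
        )
    df[col] = vals.astype(np.int64)


def read_phenology(path: str | Path) -> list[PhenologySeries]:
    """Read ``phenology.csv`` and group it into per-(species, season) census series."""
    df = _read(path, PHENOLOGY_COLUMNS)
    _int_column(df, "n_flowering", str(path), minimum=0)
    _int_column(df, "n_sampled", str(path), minimum=1)
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"invalid ISO-8601 date: {exc}", file=str(path),
                          column="date") from None
    out = []
    for (sp, season), g in df.groupby(["species", "season"], sort=True):
        g = g.sort_values("date")
        try:
            out.append(PhenologySeries(
                species=str(sp), season=str(season),
                dates=g["date"].to_numpy(dtype="datetime64[D]"),
                n_flowering=g["n_flowering"].to_numpy(),
                n_sampled=g["n_sampled"].to_numpy(),
            ))
        except ValueError as exc:
            raise SchemaError(str(exc), file=str(path), column="species") from None
    return out


def read_morphology(path: str | Path) -> pd.DataFrame:
    df = _read(path, MORPHOLOGY_COLUMNS)
    for col in MORPHOLOGY_COLUMNS[3:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        if bad.any():
            raise SchemaError("trait values must be positive numbers (mm)",
                              file=str(path), row=int(bad.idxmax()) + 2, column=col)
        df[col] = vals
    return df


def read_positions(path: str | Path) -> dict[str, str]:
    df = _read(path, POSITION_COLUMNS)
    if df["species"].duplicated().any():
        raise SchemaError("duplicate species", file=str(path), column="species")
    return dict(zip(df["species"], df["position_category"]))


def read_crosses(path: str | Path) -> pd.DataFrame:
    df = _read(path, CROSS_COLUMNS)
    _int_column(df, "flowers_pollinated", str(path), minimum=1)
    _int_column(df, "fruits_set", str(path), minimum=0)
    return df


def read_seeds(path: str | Path) -> pd.DataFrame:
    df = _read(path, SEED_COLUMNS)
    _int_column(df, "n_seeds", str(path), minimum=0)
    return df


def read_germination(path: str | Path) -> pd.DataFrame:
    df = _read(path, GERMINATION_COLUMNS)
    _int_column(df, "seeds_sown", str(path), minimum=1)
    _int_column(df, "seeds_germinated", str(path), minimum=0)
    return df


def read_barriers(path: str | Path) -> pd.DataFrame:
    df = _read(path, BARRIER_COLUMNS)
    df["strength"] = pd.to_numeric(df["strength"], errors="coerce")
    out_of_range = df["strength"].notna() & ((df["strength"] < -1) | (df["strength"] > 1))
    if out_of_range.any():
        raise SchemaError("barrier strengths must lie in [-1, 1] or be NA",
                          file=str(path), row=int(out_of_range.idxmax()) + 2,
                          column="strength")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as CSV with ``NA`` for missing values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="NA")
    return path
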
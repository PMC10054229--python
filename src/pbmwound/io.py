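"""CSV / PNG input-output with schema validation.

All tables are UTF-8 CSV with a header row and "." as the decimal separator.
Units are fixed at the I/O boundary: mm² (area), mm (perimeter/depth),
integer days, seconds, °C.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import DataError, SchemaError

WOUNDS_COLUMNS = ["animal_id", "group", "day", "area_mm2", "perimeter_mm", "depth_mm"]
TEMPS_COLUMNS = [
    "animal_id", "group", "session_day", "t_s", "surface_C", "core_pre_C", "core_post_C"
]


def _check_schema(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: schema mismatch; missing columns {missing}, extra columns {extra}"
        )


def read_wounds(path) -> pd.DataFrame:
    """Read and validate a wound-measurement table.

    Rows with negative area, non-positive perimeter (at positive area) or an
    unparseable day are rejected with their line numbers (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _check_schema(df, WOUNDS_COLUMNS, path)
    bad = []
    area = pd.to_numeric(df["area_mm2"], errors="coerce")
    perim = pd.to_numeric(df["perimeter_mm"], errors="coerce")
    day = pd.to_numeric(df["day"], errors="coerce")
    for i in df.index:
        problems = []
        if not np.isfinite(area[i]) or area[i] < 0:
            problems.append(f"area_mm2={df['area_mm2'][i]!r}")
        if not np.isfinite(perim[i]) or (area[i] > 0 and perim[i] <= 0):
            problems.append(f"perimeter_mm={df['perimeter_mm'][i]!r}")
        if not np.isfinite(day[i]) or day[i] != int(day[i]):
            problems.append(f"day={df['day'][i]!r}")
        if problems:
            bad.append(f"line {i + 2}: " + ", ".join(problems))
    if bad:
        raise DataError(f"{path}: invalid rows:\n" + "\n".join(bad))
    df["day"] = day.astype(int)
    df["area_mm2"] = area
    df["perimeter_mm"] = perim
    df["depth_mm"] = pd.to_numeric(df["depth_mm"], errors="coerce")
    return df


def write_wounds(df: pd.DataFrame, path) -> None:
    df.loc[:, WOUNDS_COLUMNS].to_csv(path, index=False)


def read_temps(path) -> pd.DataFrame:
    """Read and validate a temperature-session table.

    Core pre/post temperatures appear on each animal's t=0 row only; other
    rows leave those fields empty.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _check_schema(df, TEMPS_COLUMNS, path)
    for col in ("t_s", "surface_C"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = [f"line {i + 2}: {col}={df[col][i]!r}" for i in df.index if not np.isfinite(vals[i])]
        if bad:
            raise DataError(f"{path}: invalid rows:\n" + "\n".join(bad))
        df[col] = vals
    for col in ("core_pre_C", "core_post_C"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_temps(df: pd.DataFrame, path) -> None:
    df.loc[:, TEMPS_COLUMNS].to_csv(path, index=False)


def write_image(array: np.ndarray, path) -> None:
    """Write an 8-bit image (RGB or single-channel mask) as PNG."""
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr.astype(np.uint8)).save(path)


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path))


def read_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127
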
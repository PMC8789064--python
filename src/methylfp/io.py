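"""Plate CSV reading and writing.

The documented dialect: UTF-8 CSV with a header row and columns

    well,row,col,mP,FI,role,compound_id,compound_conc

('.' decimal separator).  ``well`` is a 384-well id (row A-P, column 1-24),
``role`` one of pos_ctrl/neg_ctrl/sample/blank.  Unknown extra columns are
preserved through a read/write round trip.  Real plate-reader exports vary by
vendor; this dialect is the package's own, intended as an export target rather
than a parser of any instrument's native file.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import PlateSchemaError, ValidationError
from .screening import PLATE_COLUMNS, PlateRead, parse_well

__all__ = ["read_plate_csv", "write_plate_csv"]

_CSV_RENAME = {"mP": "mp", "FI": "fi"}
_REQUIRED = ["well", "row", "col", "mP", "FI", "role", "compound_id",
             "compound_conc"]


def read_plate_csv(path) -> PlateRead:
    """Read a plate CSV into a :class:`PlateRead`.

    Malformed well ids, duplicate wells and missing mP values raise
    :class:`PlateSchemaError` naming the offending CSV line numbers (the
    header is line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise PlateSchemaError(f"{path}: missing required columns {missing}")

    def lineno(i: int) -> int:
        return int(i) + 2  # header on line 1, first data row on line 2

    for i, well in df["well"].items():
        try:
            parse_well(well)
        except ValidationError as exc:
            raise PlateSchemaError(f"{path}, line {lineno(i)}: {exc}") from exc
    dup = df["well"].duplicated(keep=False)
    if dup.any():
        lines = [lineno(i) for i in df.index[dup]]
        raise PlateSchemaError(f"{path}: duplicate wells on lines {lines}")
    bad_mp = df["mP"].isna() & (df["role"] != "blank")
    if bad_mp.any():
        lines = [lineno(i) for i in df.index[bad_mp]]
        raise PlateSchemaError(f"{path}: missing mP on lines {lines}")

    df = df.rename(columns=_CSV_RENAME).set_index("well")
    df["compound_id"] = df["compound_id"].fillna("")
    extras = [c for c in df.columns if c not in PLATE_COLUMNS]
    try:
        return PlateRead(df[PLATE_COLUMNS + extras])
    except ValidationError as exc:
        raise PlateSchemaError(f"{path}: {exc}") from exc


def write_plate_csv(plate: PlateRead, path) -> None:
    """Write a :class:`PlateRead` in the documented CSV dialect (lossless)."""
    df = plate.wells.rename(columns={"mp": "mP", "fi": "FI"})
    df.index.name = "well"
    df.to_csv(Path(path), index=True)
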
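"""Table and report I/O with strict, stable file contracts.

Delimited-text dialect: comma-separated, UTF-8, header row required,
"." decimal, "NA" missing token; tab-separated input is accepted by
sniffing the header line.  Writers never reorder rows.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from cordmapper.errors import DataError

NA_TOKEN = "NA"

CELLS_COLUMNS = ["cell_id", "section_id", "population", "markers", "D", "alpha_deg"]
SECTIONS_COLUMNS = ["section_id", "embryo_id", "group", "stage", "axial_level",
                    "side", "H", "W", "unit"]
COUNTS_COLUMNS = ["embryo_id", "group", "axial_level", "section_id",
                  "population", "count"]

_NUMERIC = {"D": float, "alpha_deg": float, "H": float, "W": float,
            "count": "Int64", "dv": float, "ml": float}


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV/TSV table, enforcing the required columns and types.

    Raises :class:`~cordmapper.errors.DataError` naming the file and the
    missing column or unparseable field.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: file not found")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, na_values=[NA_TOKEN], keep_default_na=False,
                     dtype=str, encoding="utf-8")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DataError(f"{path}: missing required column(s) {missing}")
    for col, typ in _NUMERIC.items():
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
                if typ is float:
                    df[col] = df[col].astype(float)
            except (ValueError, TypeError) as exc:
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                              & df[col].notna()]
                line = int(bad.index[0]) + 2 if len(bad) else "?"
                raise DataError(
                    f"{path}: column {col!r}, line {line}: not numeric"
                ) from exc
    if "outlier_flag" in df.columns:
        df["outlier_flag"] = df["outlier_flag"].map(
            {"True": True, "False": False, "true": True, "false": False}
        ).astype(bool)
    return df


def read_cells(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=CELLS_COLUMNS)


def read_sections(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=SECTIONS_COLUMNS)


def read_counts(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=COUNTS_COLUMNS)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as UTF-8 CSV with NA for missing, preserving row order."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep=NA_TOKEN, encoding="utf-8")


def read_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: config file not found")
    with open(path, "r", encoding="utf-8") as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh) or {}
        return json.load(fh)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
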
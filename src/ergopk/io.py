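"""Tabular I/O, config handling, and run manifests.

Single tabular dialect: CSV, UTF-8, header row, '.' decimal separator.
Concentration files carry ``time_h``, ``matrix``, ``concentration_uM``
(plus optional grouping columns); concentrations are always μM.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conversions import blood_to_rbc
from .simulate import MATRICES, ConcentrationSeries

__all__ = [
    "SchemaError",
    "read_concentration_csv",
    "write_concentration_csv",
    "format_projection_table",
    "write_projection_table",
    "write_manifest",
]


class SchemaError(ValueError):
    """Input file violates the documented schema; names row and column."""


REQUIRED_COLUMNS = ("time_h", "matrix", "concentration_uM")


def read_concentration_csv(path: str | Path, hct: float | None = None) -> pd.DataFrame:
    """Read and validate a concentration CSV.

    Unknown matrix labels and negative concentrations are rejected with the
    offending row index.  When whole-blood rows are present and ``hct`` is
    supplied, matching plasma rows are used to derive RBC records (appended
    with matrix ``rbc``) via the hematocrit mass balance.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    bad_matrix = ~df["matrix"].isin(MATRICES)
    if bad_matrix.any():
        row = int(df.index[bad_matrix][0])
        raise SchemaError(
            f"{path.name}: row {row}, column 'matrix': unknown label {df.loc[row, 'matrix']!r}"
        )
    conc = pd.to_numeric(df["concentration_uM"], errors="coerce")
    bad_conc = conc.isna() | (conc < 0)
    if bad_conc.any():
        row = int(df.index[bad_conc][0])
        raise SchemaError(
            f"{path.name}: row {row}, column 'concentration_uM': "
            f"invalid value {df.loc[row, 'concentration_uM']!r}"
        )
    df["concentration_uM"] = conc

    has_blood = (df["matrix"] == "blood").any()
    if has_blood and hct is not None:
        group_cols = [c for c in df.columns if c not in ("matrix", "concentration_uM")]
        wide = df.pivot_table(
            index=group_cols, columns="matrix", values="concentration_uM"
        )
        if "plasma" in wide.columns:
            pair = wide.dropna(subset=["blood", "plasma"])
            derived = pair.reset_index()
            derived["concentration_uM"] = blood_to_rbc(
                pair["blood"].to_numpy(), pair["plasma"].to_numpy(), hct
            )
            derived["matrix"] = "rbc"
            derived = derived[list(group_cols) + ["matrix", "concentration_uM"]]
            df = pd.concat([df, derived], ignore_index=True)
    return df


def write_concentration_csv(series: ConcentrationSeries, path: str | Path) -> None:
    """Write a simulated series (full double precision; lossless round-trip)."""
    series.data.to_csv(path, index=False)


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return float(np.format_float_positional(
        x, precision=sig, unique=False, fractional=False, trim="k"
    ))


def format_projection_table(table: pd.DataFrame, sig: int = 3) -> pd.DataFrame:
    """Pivot the tidy dose-projection table to the printed layout.

    Rows are (initial plasma, dose), columns are weeks; cells rounded to
    ``sig`` significant figures as displayed in print.
    """
    expected = {"init_plasma_uM", "dose_mg", "week", "plasma_uM"}
    missing = expected - set(table.columns)
    if missing:
        raise ValueError(f"dose table missing column(s): {sorted(missing)}")
    n_blocks = table["init_plasma_uM"].nunique()
    n_doses = table["dose_mg"].nunique()
    n_weeks = table["week"].nunique()
    if len(table) != n_blocks * n_doses * n_weeks:
        raise ValueError("incomplete dose table: expected a full block × dose × week grid")
    out = table.copy()
    out["plasma_uM"] = out["plasma_uM"].map(lambda v: _round_sig(v, sig))
    wide = out.pivot_table(
        index=["init_plasma_uM", "dose_mg"], columns="week", values="plasma_uM"
    )
    wide.columns = [f"week_{int(w)}" for w in wide.columns]
    return wide.reset_index()


def write_projection_table(table: pd.DataFrame, path: str | Path, sig: int = 3) -> None:
    format_projection_table(table, sig).to_csv(path, index=False)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    command: str,
    options: dict,
    inputs: dict[str, str | Path] | None = None,
    seed: int | None = None,
) -> Path:
    """Write a machine-readable manifest enabling exact re-runs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "options": {k: (str(v) if isinstance(v, Path) else v) for k, v in options.items()},
        "seed": seed,
        "input_checksums": {
            name: _digest(p) for name, p in (inputs or {}).items() if Path(p).exists()
        },
        "versions": {
            "ergopk": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path
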
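"""CSV report writers and readers for the account tables.

Account CSVs mirror the published layout: one row per account line, one
column per SEEA class (codes 1-14). Cells are integer km² or tonnes, rounded
half-away-from-zero at write time only; explicitly unknown or absent cells
(opening soil stocks, sealing, Mangrove in Europe) are written as empty/NA,
never as 0. A leading comment line records package version, config hash and
seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import round_half_away
from .extent import ACCOUNT_ROWS, ExtentAccount
from .mass import MASS_ROWS, MassAccount
from .nomenclature import SEEA_CODES


def _provenance_line(config: dict | None, seed: int | None) -> str:
    cfg_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return f"# soilcap {__version__} config_hash={cfg_hash} seed={seed}"


def _fmt(v: float, missing: str) -> str:
    if pd.isna(v):
        return missing
    return str(round_half_away(float(v)))


def write_account_csv(
    table: pd.DataFrame,
    path: str | Path,
    missing: str = "NA",
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write a line-by-class account table as integer CSV."""
    with open(path, "w") as fh:
        fh.write(_provenance_line(config, seed) + "\n")
        fh.write("line," + ",".join(str(c) for c in table.columns) + "\n")
        for row in table.index:
            cells = [_fmt(table.at[row, c], missing) for c in table.columns]
            fh.write(row + "," + ",".join(cells) + "\n")


def read_account_csv(path: str | Path, missing: str = "NA") -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", index_col=0, na_values=[missing, ""])
    df.columns = [int(c) for c in df.columns]
    df.index.name = None
    return df.astype(float)


def write_extent_csv(acct: ExtentAccount, path: str | Path, **kwargs) -> None:
    write_account_csv(acct.table, path, **kwargs)


def read_extent_csv(path: str | Path) -> ExtentAccount:
    table = read_account_csv(path)
    return ExtentAccount(table.reindex(index=list(ACCOUNT_ROWS), columns=list(SEEA_CODES)))


def write_mass_csv(acct: MassAccount, path: str | Path, **kwargs) -> None:
    write_account_csv(acct.rounded(), path, missing="", **kwargs)


def read_mass_csv(path: str | Path) -> pd.DataFrame:
    return read_account_csv(path, missing="").reindex(
        index=list(MASS_ROWS), columns=list(SEEA_CODES)
    )


def write_crosstab_csv(
    tab: pd.DataFrame, path: str | Path, config: dict | None = None, seed: int | None = None
) -> None:
    """Crosstab CSV: covers as rows, condition classes as columns, area in ha
    (full precision — these are estimates, not ledger integers)."""
    with open(path, "w") as fh:
        fh.write(_provenance_line(config, seed) + "\n")
        tab.to_csv(fh, float_format="%.6f")


def read_crosstab_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)


def load_extent_inputs(path: str | Path | None = None) -> tuple[pd.Series, pd.Series]:
    """Read (opening areas, net changes) km² from a fixture-style CSV.

    Columns: seea_code, opening_km2, net_change_km2; NA marks classes absent
    from the territory. Defaults to the packaged EU-25 2000-2012 inputs.
    """
    if path is None:
        from importlib import resources

        path = resources.files("soilcap").joinpath("fixtures/extent_eu25_2000_2012.csv")
    df = pd.read_csv(str(path), comment="#", na_values=["NA"])
    opening = pd.Series(df["opening_km2"].to_numpy(), index=df["seea_code"].to_numpy())
    net = pd.Series(df["net_change_km2"].to_numpy(), index=df["seea_code"].to_numpy())
    return opening, net.fillna(0.0)
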
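"""Soil mass-balance accounts per land-cover class.

Additions to the soil stock are formation (bounded below and above by
per-hectare formation rates, default 0.4-1.4 t ha⁻¹ from cosmogenic-nuclide
production estimates) plus deposition of eroded material redistributed on
land. Reductions are the eroded mass itself, split between redeposition on
land and loss to watercourses by a delivery fraction (the sediment delivery
ratio at the accounting scale). Because within-land redistribution is
mass-neutral (deposition = redeposited), the closing stock change reduces to

    closing_high = formation_high − lost
    closing_low  = formation_low  − lost

Opening stocks are unknown (left blank), so "closing" is the net change over
the period. All masses are computed in full precision; integer tonnes appear
only at report time, rounding the lost mass first and giving redeposited the
remainder so the pair always sums exactly to the gross erosion mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import round_half_away
from .nomenclature import SEEA_CLASSES, SEEA_CODES

#: SEEA classes with soil mass flows. Artificial surfaces, mangrove, aquatic
#: vegetation, permanent snow, and water bodies carry none.
ACCOUNTED_CLASSES: tuple[int, ...] = (2, 3, 4, 5, 6, 8, 10, 11)

MASS_ROWS = (
    "opening_stock",
    "formation_high",
    "formation_low",
    "deposition",
    "upward_reappraisal",
    "total_additions_high",
    "sealed",
    "redeposited",
    "lost",
    "downward_reappraisal",
    "total_reductions",
    "closing_high",
    "closing_low",
)


@dataclass(frozen=True)
class FormationRates:
    """Lower and upper bounds on soil formation, t ha⁻¹ (per accounting step)."""

    low: float = 0.4
    high: float = 1.4

    def __post_init__(self) -> None:
        if not (0 <= self.low <= self.high):
            raise ValueError(f"need 0 <= low <= high, got {self.low}, {self.high}")


@dataclass
class ErosionParams:
    """Per-class gross (rill + sheet) erosion rates and the delivery fraction.

    ``gross_rates`` maps SEEA code -> t ha⁻¹; ``delivery_fraction`` is the
    share of gross erosion delivered to watercourses rather than redeposited
    on land.
    """

    gross_rates: dict[int, float]
    delivery_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 <= self.delivery_fraction <= 1):
            raise ValueError(f"delivery_fraction must be in [0, 1], got {self.delivery_fraction}")
        bad = {k: v for k, v in self.gross_rates.items() if v < 0}
        if bad:
            raise ValueError(f"gross erosion rates must be >= 0: {bad}")


@dataclass
class MassAccount:
    """Mass account table: rows = account lines (t), columns = SEEA classes.

    NaN marks unknown or not-accounted cells (opening stocks, sealing, and the
    six classes without mass flows); they serialize as empty, never 0.
    """

    table: pd.DataFrame
    rates: FormationRates
    erosion: ErosionParams
    epoch: str = ""

    def __post_init__(self) -> None:
        self.table = self.table.reindex(index=list(MASS_ROWS), columns=list(SEEA_CODES))

    def rounded(self) -> pd.DataFrame:
        """Integer-tonne view with the exact-sum rounding rule.

        ``lost`` is rounded half-away-from-zero first and ``redeposited``
        takes the remainder of the rounded gross mass, so the pair always sums
        to gross. Totals are sums of the rounded components (so the
        conservation identity additions − reductions = formation_high − lost
        holds exactly in integer tonnes); closing rows round from the
        full-precision balance.
        """
        out = self.table.copy()
        for col in out.columns:
            if out[col].isna().all():
                continue
            gross_r = float(round_half_away(out.at["redeposited", col] + out.at["lost", col]))
            lost_r = float(round_half_away(out.at["lost", col]))
            redep_r = gross_r - lost_r
            f_hi_r = float(round_half_away(out.at["formation_high", col]))
            f_lo_r = float(round_half_away(out.at["formation_low", col]))
            out.at["lost", col] = lost_r
            out.at["redeposited", col] = redep_r
            out.at["deposition", col] = redep_r
            out.at["formation_high", col] = f_hi_r
            out.at["formation_low", col] = f_lo_r
            out.at["upward_reappraisal", col] = 0.0
            out.at["downward_reappraisal", col] = 0.0
            out.at["total_additions_high", col] = f_hi_r + redep_r
            out.at["total_reductions", col] = redep_r + lost_r
            out.at["closing_high", col] = float(round_half_away(self.table.at["closing_high", col]))
            out.at["closing_low", col] = float(round_half_away(self.table.at["closing_low", col]))
        return out


def formation_mass(area_ha: float, rate: float) -> float:
    """Soil mass formed (t) over ``area_ha`` hectares at ``rate`` t ha⁻¹."""
    if area_ha < 0:
        raise ValueError(f"area must be >= 0, got {area_ha}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return area_ha * rate


def partition_erosion(gross: float, delivery_fraction: float) -> tuple[float, float]:
    """Split gross eroded mass into (redeposited on land, lost to watercourses).

    lost = round(delivery_fraction × gross) to integer tonnes; redeposited is
    the remainder against rounded gross, so the pair sums exactly.
    """
    if gross < 0:
        raise ValueError(f"gross erosion must be >= 0, got {gross}")
    if not (0 <= delivery_fraction <= 1):
        raise ValueError(f"delivery fraction must be in [0, 1], got {delivery_fraction}")
    lost = float(round_half_away(delivery_fraction * gross))
    redeposited = float(round_half_away(gross)) - lost
    return redeposited, lost


def build_mass_account(
    areas_ha: dict[int, float] | pd.Series,
    rates: FormationRates | None = None,
    erosion: ErosionParams | None = None,
    years: float = 1.0,
    epoch: str = "",
) -> MassAccount:
    """Assemble the per-class mass account.

    ``areas_ha`` must cover every accounted class (2, 3, 4, 5, 6, 8, 10, 11).
    ``years`` scales all flows (default 1: one application of the per-hectare
    rates, which is how the published prototype table is laid out even though
    it is headed by a 12-year period).
    """
    rates = rates or FormationRates()
    erosion = erosion or default_erosion_params()
    if years < 0:
        raise ValueError(f"years must be >= 0, got {years}")
    areas = pd.Series(areas_ha, dtype=float)
    missing = [c for c in ACCOUNTED_CLASSES if c not in areas.index or pd.isna(areas.get(c))]
    if missing:
        raise ValueError(f"missing areas for accounted classes: {missing}")
    missing_rates = [c for c in ACCOUNTED_CLASSES if c not in erosion.gross_rates]
    if missing_rates:
        raise ValueError(f"missing gross erosion rates for classes: {missing_rates}")
    if (areas.reindex(ACCOUNTED_CLASSES) < 0).any():
        raise ValueError("areas must be >= 0")

    table = pd.DataFrame(np.nan, index=list(MASS_ROWS), columns=list(SEEA_CODES))
    for c in ACCOUNTED_CLASSES:
        area = float(areas[c]) * years
        f_hi = formation_mass(area, rates.high)
        f_lo = formation_mass(area, rates.low)
        gross = area * erosion.gross_rates[c]
        lost_raw = erosion.delivery_fraction * gross
        redep_raw = gross - lost_raw
        table.loc["formation_high", c] = f_hi
        table.loc["formation_low", c] = f_lo
        table.loc["deposition", c] = redep_raw
        table.loc["redeposited", c] = redep_raw
        table.loc["lost", c] = lost_raw
        table.loc["upward_reappraisal", c] = 0.0
        table.loc["downward_reappraisal", c] = 0.0
        table.loc["total_additions_high", c] = f_hi + redep_raw
        table.loc["total_reductions", c] = gross
        table.loc["closing_high", c] = f_hi - lost_raw
        table.loc["closing_low", c] = f_lo - lost_raw
    return MassAccount(table, rates=rates, erosion=erosion, epoch=epoch)


def net_balance_summary(acct: MassAccount) -> pd.DataFrame:
    """Per-class net balance (formation_high − gross erosion) and depletion flag.

    A class is flagged depleting when even the optimistic formation bound
    cannot offset the erosive loss, i.e. closing_high < 0.
    """
    t = acct.table
    rows = []
    for c in SEEA_CODES:
        if t[c].isna().all() or pd.isna(t.at["formation_high", c]):
            rows.append((c, SEEA_CLASSES[c], np.nan, False))
            continue
        gross = t.at["redeposited", c] + t.at["lost", c]
        net = t.at["formation_high", c] - gross
        rows.append((c, SEEA_CLASSES[c], net, bool(t.at["closing_high", c] < 0)))
    out = pd.DataFrame(rows, columns=["seea_code", "class_name", "net_balance_t", "depleting"])
    return out.set_index("seea_code")


def depth_rate_to_mass_rate(depth_rate_mm: float, bulk_density: float) -> float:
    """Convert a soil-formation depth rate (mm yr⁻¹) to a mass rate (t ha⁻¹ yr⁻¹).

    1 mm of soil over 1 ha is 10 m³, so mass rate = depth × 10 × bulk density
    (t m⁻³).
    """
    if depth_rate_mm <= 0:
        raise ValueError(f"depth rate must be > 0, got {depth_rate_mm}")
    if bulk_density <= 0:
        raise ValueError(f"bulk density must be > 0, got {bulk_density}")
    return depth_rate_mm * 10.0 * bulk_density


def load_mass_inputs(path: str | Path | None = None) -> tuple[pd.Series, ErosionParams]:
    """Read per-class areas and gross erosion rates from CSV.

    Columns: seea_code, area_ha, gross_rate_t_per_ha. Defaults to the packaged
    EU-25 fixture (areas and rates implied by the published prototype table).
    """
    if path is None:
        path = resources.files("soilcap").joinpath("fixtures/mass_inputs_eu25.csv")
    df = pd.read_csv(str(path), comment="#")
    areas = pd.Series(df["area_ha"].to_numpy(), index=df["seea_code"].to_numpy())
    rates = dict(zip(df["seea_code"], df["gross_rate_t_per_ha"]))
    return areas, ErosionParams(gross_rates=rates)


def default_erosion_params() -> ErosionParams:
    return load_mass_inputs()[1]
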
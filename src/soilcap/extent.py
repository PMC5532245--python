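"""Land-cover change matrices and SEEA extent accounts.

The extent account records, per SEEA class, the opening area, additions to
stock (managed/natural expansion, upward reappraisals), reductions in stock
(managed/natural regression, downward reappraisals; stored non-positive) and
the closing area, with the identity

    closing = opening + total_additions + total_reductions

holding exactly for every class. All areas are carried in km² at full
precision; rounding to integer km² happens only when a report is written.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import NODATA, LandCoverGrid, area_by_class
from .nomenclature import SEEA_CLASSES, SEEA_CODES

#: Classes under direct economic management: artificial surfaces and the
#: three cropped systems. Woodland is deliberately not split (partly managed,
#: partly not), so its changes are recorded as natural.
DEFAULT_MANAGED_CLASSES = frozenset({1, 2, 3, 4})

ADDITION_ROWS = ("managed_expansion", "natural_expansion", "upward_reappraisal")
REDUCTION_ROWS = ("managed_regression", "natural_regression", "downward_reappraisal")
ACCOUNT_ROWS = (
    "opening",
    *ADDITION_ROWS,
    "total_additions",
    *REDUCTION_ROWS,
    "total_reductions",
    "closing",
)


@dataclass
class ChangeMatrix:
    """14x14 table of area flows (km²) between two epochs.

    flows.loc[i, j] is the area that was class i at t0 and class j at t1.
    Row sums are the per-class areas at t0, column sums those at t1.
    """

    flows: pd.DataFrame
    epoch_pair: tuple[str, str] = ("t0", "t1")

    def __post_init__(self) -> None:
        flows = pd.DataFrame(self.flows, dtype=float)
        flows = flows.reindex(index=SEEA_CODES, columns=SEEA_CODES, fill_value=0.0)
        if (flows.to_numpy() < 0).any():
            raise ValueError("change-matrix flows must be non-negative")
        self.flows = flows

    @property
    def opening_areas(self) -> pd.Series:
        return self.flows.sum(axis=1)

    @property
    def closing_areas(self) -> pd.Series:
        return self.flows.sum(axis=0)

    @property
    def total_area(self) -> float:
        return float(self.flows.to_numpy().sum())

    def net_changes(self) -> pd.Series:
        """closing − opening per class (column sum − row sum)."""
        return self.closing_areas - self.opening_areas


def change_matrix(
    grid_t0: LandCoverGrid,
    grid_t1: LandCoverGrid,
    min_mapping_unit: float = 0.0,
) -> ChangeMatrix:
    """Tally per-cell class flows between two co-registered SEEA grids.

    Contiguous (4-connected) patches of changed cells whose total area is
    strictly smaller than ``min_mapping_unit`` (km²) are folded back into the
    diagonal, i.e. treated as unchanged — mirroring the minimum mapping unit
    applied to operational land-cover change layers. ``min_mapping_unit = 0``
    disables the filter.
    """
    if grid_t0.nomenclature != "seea" or grid_t1.nomenclature != "seea":
        raise ValueError("change_matrix requires SEEA-nomenclature grids")
    if grid_t0.shape != grid_t1.shape:
        raise ValueError(f"grid shapes differ: {grid_t0.shape} vs {grid_t1.shape}")
    if not np.isclose(grid_t0.cell_area, grid_t1.cell_area):
        raise ValueError(
            f"cell areas differ: {grid_t0.cell_area} vs {grid_t1.cell_area} km²"
        )
    discordant = int((grid_t0.nodata_mask != grid_t1.nodata_mask).sum())
    if discordant:
        raise ValueError(
            f"nodata masks differ between epochs at {discordant} cells; a cell "
            "classified in one epoch only is an error, not a flow"
        )

    c0 = grid_t0.codes.copy()
    c1 = grid_t1.codes.copy()
    valid = c0 != NODATA

    if min_mapping_unit > 0:
        changed = (c0 != c1) & valid
        labels, n_patches = ndimage.label(
            changed, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        )
        if n_patches:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_patches + 1))
            small = np.flatnonzero(sizes * grid_t0.cell_area < min_mapping_unit) + 1
            if small.size:
                fold = np.isin(labels, small)
                c1 = np.where(fold, c0, c1)

    pair = (c0[valid] - 1) * 14 + (c1[valid] - 1)
    counts = np.bincount(pair, minlength=14 * 14).reshape(14, 14)
    flows = pd.DataFrame(
        counts * grid_t0.cell_area, index=SEEA_CODES, columns=SEEA_CODES, dtype=float
    )
    return ChangeMatrix(flows, epoch_pair=(grid_t0.epoch or "t0", grid_t1.epoch or "t1"))


@dataclass
class ExtentAccount:
    """Per-class extent account in the standard SEEA layout.

    ``table`` has one row per account line (see ACCOUNT_ROWS) and one column
    per SEEA class code. NaN marks a class explicitly absent from the
    accounted territory (serialized as "NA", never as 0).
    """

    table: pd.DataFrame
    mode: str = "net"
    epoch_pair: tuple[str, str] = ("t0", "t1")

    def __post_init__(self) -> None:
        self.table = self.table.reindex(index=list(ACCOUNT_ROWS), columns=list(SEEA_CODES))

    @property
    def opening(self) -> pd.Series:
        return self.table.loc["opening"]

    @property
    def closing(self) -> pd.Series:
        return self.table.loc["closing"]

    def check_identity(self, atol: float = 1e-9) -> None:
        t = self.table.fillna(0.0)
        resid = t.loc["closing"] - (
            t.loc["opening"] + t.loc["total_additions"] + t.loc["total_reductions"]
        )
        if (resid.abs() > atol).any():
            raise AssertionError(f"account identity violated: residuals {resid.to_dict()}")


def _assemble_account(
    opening: pd.Series,
    additions: pd.Series,
    reductions: pd.Series,
    managed_classes: frozenset[int] | set[int],
    mode: str,
    epoch_pair: tuple[str, str],
    absent: pd.Series | None = None,
) -> ExtentAccount:
    managed = opening.index.isin(sorted(managed_classes))
    zero = pd.Series(0.0, index=opening.index)
    table = pd.DataFrame(
        {
            "opening": opening,
            "managed_expansion": additions.where(managed, 0.0),
            "natural_expansion": additions.where(~managed, 0.0),
            "upward_reappraisal": zero,
            "managed_regression": reductions.where(managed, 0.0),
            "natural_regression": reductions.where(~managed, 0.0),
            "downward_reappraisal": zero,
        }
    ).T
    table.loc["total_additions"] = table.loc[list(ADDITION_ROWS)].sum()
    table.loc["total_reductions"] = table.loc[list(REDUCTION_ROWS)].sum()
    table.loc["closing"] = (
        table.loc["opening"] + table.loc["total_additions"] + table.loc["total_reductions"]
    )
    if absent is not None:
        table.loc[:, absent] = np.nan
    acct = ExtentAccount(table, mode=mode, epoch_pair=epoch_pair)
    acct.check_identity()
    return acct


def build_extent_account(
    cm: ChangeMatrix,
    opening_areas: dict[int, float] | pd.Series | None = None,
    managed_classes: frozenset[int] | set[int] = DEFAULT_MANAGED_CLASSES,
    mode: str = "net",
    atol: float = 1e-6,
) -> ExtentAccount:
    """Build an extent account from a change matrix.

    In ``net`` mode each class records only its net flow (column sum − row
    sum), as expansion if positive or regression if negative — the layout used
    in published SEEA tables. ``gross`` mode records total inflow and outflow
    separately (off-diagonal column/row sums), since netting can hide
    substantial two-way change. Flows of managed classes are booked under the
    managed_* lines, all others under natural_*. Reappraisal lines are kept in
    the layout but are always 0 here.
    """
    if mode not in ("net", "gross"):
        raise ValueError(f"mode must be 'net' or 'gross', got {mode!r}")

    row_sums = cm.opening_areas
    if opening_areas is None:
        opening = row_sums.astype(float)
    else:
        opening = pd.Series(opening_areas, dtype=float).reindex(list(SEEA_CODES))
        resid = (opening.fillna(0.0) - row_sums).abs()
        if (resid > atol).any():
            bad = resid[resid > atol]
            raise ValueError(
                "opening areas inconsistent with change-matrix row sums; "
                f"per-class residuals (km²): {bad.to_dict()}"
            )

    if mode == "net":
        net = cm.net_changes()
        additions = net.clip(lower=0.0)
        reductions = net.clip(upper=0.0)
    else:
        diag = pd.Series(np.diag(cm.flows.to_numpy()), index=list(SEEA_CODES))
        additions = cm.closing_areas - diag
        reductions = -(cm.opening_areas - diag)

    # a class with no opening area and no flows at all is absent from the
    # territory (e.g. Mangrove in Europe) and reports NA, not 0
    absent = (opening.fillna(0.0) == 0) & (additions == 0) & (reductions == 0)
    return _assemble_account(
        opening.fillna(0.0), additions, reductions, managed_classes, mode,
        cm.epoch_pair, absent=absent,
    )


def extent_account_from_net_changes(
    opening_areas: dict[int, float] | pd.Series,
    net_changes: dict[int, float] | pd.Series,
    managed_classes: frozenset[int] | set[int] = DEFAULT_MANAGED_CLASSES,
    epoch_pair: tuple[str, str] = ("t0", "t1"),
) -> ExtentAccount:
    """Build a net-mode account directly from opening areas and net flows.

    This is the entry point for published accounts where only per-class net
    changes (not the full transition matrix) are available. Classes whose
    opening area is NaN are carried as explicitly absent (NA).
    """
    opening = pd.Series(opening_areas, dtype=float).reindex(list(SEEA_CODES))
    net = pd.Series(net_changes, dtype=float).reindex(list(SEEA_CODES)).fillna(0.0)
    absent = opening.isna() & (net == 0)
    additions = net.clip(lower=0.0)
    reductions = net.clip(upper=0.0)
    return _assemble_account(
        opening.fillna(0.0), additions, reductions, managed_classes, "net",
        epoch_pair, absent=absent,
    )


def net_change_summary(acct: ExtentAccount, total_area: float) -> pd.DataFrame:
    """Net change per class in km² and as a percentage of total territory."""
    if total_area <= 0:
        raise ValueError(f"total_area must be > 0, got {total_area}")
    net = acct.table.loc["closing"] - acct.table.loc["opening"]
    out = pd.DataFrame(
        {
            "class_name": [SEEA_CLASSES[c] for c in SEEA_CODES],
            "net_km2": net.to_numpy(),
            "net_pct": 100.0 * net.to_numpy() / total_area,
        },
        index=list(SEEA_CODES),
    )
    out.index.name = "seea_code"
    return out
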
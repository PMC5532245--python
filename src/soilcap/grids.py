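"""Categorical land-cover grids and their file formats.

A grid is a 2-D integer array of land-cover codes (0 = nodata) in either the
CORINE or the SEEA nomenclature, plus the area of one cell in km². The text
format is a small ESRI-ASCII-like header (ncols, nrows, cellsize_m, nodata)
followed by rows of integer codes; single-band integer TIFF is also accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .nomenclature import CORINE_TO_SEEA, SEEA_CLASSES, ClassMapping

NODATA = 0


@dataclass
class LandCoverGrid:
    """One epoch of categorical land cover on a regular grid."""

    codes: np.ndarray
    cell_area: float  # km² per cell
    epoch: str = ""
    nomenclature: str = "seea"  # "seea" | "corine"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2:
            raise ValueError(f"grid must be 2-D, got shape {self.codes.shape}")
        if self.cell_area <= 0:
            raise ValueError(f"cell_area must be > 0, got {self.cell_area}")
        if self.nomenclature not in ("seea", "corine"):
            raise ValueError(f"unknown nomenclature {self.nomenclature!r}")
        valid = set(SEEA_CLASSES) if self.nomenclature == "seea" else set(CORINE_TO_SEEA)
        present = set(np.unique(self.codes).tolist()) - {NODATA}
        bad = present - valid
        if bad:
            raise ValueError(
                f"codes not valid in {self.nomenclature} nomenclature: {sorted(bad)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.codes == NODATA

    def copy_with(self, **kwargs) -> "LandCoverGrid":
        return replace(self, **kwargs)


def aggregate_classes(grid: LandCoverGrid, mapping: ClassMapping | None = None) -> LandCoverGrid:
    """Reclassify a CORINE-coded grid to the 14 SEEA classes.

    Nodata (0) cells pass through unchanged; shape and nodata mask are
    preserved. Raises if the grid is already SEEA (the no-op must be explicit)
    or if any non-zero code is missing from the mapping.
    """
    if grid.nomenclature != "corine":
        raise ValueError(
            "aggregate_classes expects a CORINE grid; input is already in the "
            "SEEA nomenclature"
        )
    mapping = mapping or ClassMapping.default()
    codes = grid.codes
    present = np.unique(codes)
    unknown = [int(c) for c in present if c != NODATA and c not in mapping]
    if unknown:
        counts = {c: int((codes == c).sum()) for c in unknown}
        raise ValueError(f"CORINE codes missing from mapping (code: cell count): {counts}")
    # lookup table over the code range; CLC codes are 3-digit
    lut = np.zeros(int(codes.max()) + 1 if codes.size else 1, dtype=np.int64)
    for corine in present:
        if corine != NODATA:
            lut[corine] = mapping[int(corine)]
    out = lut[codes]
    return LandCoverGrid(out, grid.cell_area, epoch=grid.epoch, nomenclature="seea")


def area_by_class(grid: LandCoverGrid) -> dict[int, float]:
    """Area (km²) of each of the 14 SEEA classes; absent classes report 0."""
    if grid.nomenclature != "seea":
        raise ValueError("area_by_class expects a SEEA grid")
    counts = np.bincount(grid.codes.ravel(), minlength=15)
    return {k: float(counts[k]) * grid.cell_area for k in SEEA_CLASSES}


# --- text grid format ------------------------------------------------------

def write_text_grid(grid: LandCoverGrid, path: str | Path) -> None:
    nrows, ncols = grid.shape
    cellsize_m = float(np.sqrt(grid.cell_area * 1e6))
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"cellsize_m {cellsize_m:.6f}\n")
        fh.write(f"nodata {NODATA}\n")
        fh.write(f"nomenclature {grid.nomenclature}\n")
        fh.write(f"epoch {grid.epoch}\n")
        for row in grid.codes:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_text_grid(path: str | Path) -> LandCoverGrid:
    header: dict[str, str] = {}
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if parts[0].isalpha() or parts[0] in (
                "ncols", "nrows", "cellsize_m", "nodata", "nomenclature", "epoch",
            ):
                header[parts[0]] = parts[1] if len(parts) > 1 else ""
            else:
                rows.append([int(v) for v in parts])
    for key in ("ncols", "nrows", "cellsize_m"):
        if key not in header:
            raise ValueError(f"grid file {path} missing header field {key!r}")
    codes = np.array(rows, dtype=np.int64)
    if codes.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid body shape {codes.shape} does not match header "
            f"({header['nrows']} x {header['ncols']})"
        )
    cell_area = (float(header["cellsize_m"]) / 1000.0) ** 2
    return LandCoverGrid(
        codes,
        cell_area,
        epoch=header.get("epoch", ""),
        nomenclature=header.get("nomenclature", "seea"),
    )


def read_tiff_grid(
    path: str | Path, cellsize_m: float, epoch: str = "", nomenclature: str = "seea"
) -> LandCoverGrid:
    """Read a single-band integer TIFF as a land-cover grid (0 = nodata)."""
    import tifffile

    codes = np.asarray(tifffile.imread(str(path)))
    if codes.ndim != 2:
        raise ValueError(f"expected a single-band raster, got shape {codes.shape}")
    cell_area = (cellsize_m / 1000.0) ** 2
    return LandCoverGrid(codes.astype(np.int64), cell_area, epoch=epoch, nomenclature=nomenclature)


def read_grid(path: str | Path, **kwargs) -> LandCoverGrid:
    """Dispatch on extension: .tif/.tiff via tifffile, else the text format."""
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return read_tiff_grid(path, **kwargs)
    return read_text_grid(path)
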
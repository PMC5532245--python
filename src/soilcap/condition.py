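"""Soil condition classification and area cross-tabulations.

Topsoil point samples (LUCAS-style: SOC in g/kg, pH, a map-derived peat flag)
are classified into condition classes and cross-tabulated against land cover:

* SOC classes — peat (map-defined, takes precedence over concentration),
  organo-mineral (> 12 % SOC), humus-mineral (3-12 %), mineral (< 3 %).
  Thresholds are on percent organic carbon; 12 % = 120 g/kg, 3 % = 30 g/kg.
  Both boundary values fall in humus-mineral ("> 12 %" and "< 3 %" strict).
* pH classes — six bins with breakpoints 4.5, 5, 6, 7, 8.3. Bins are
  lower-inclusive except the top of "7-8.3", which is closed because "> 8.3"
  is strict (8.3 itself is the upper limit of normal exchange chemistry;
  above it boron toxicity and sodicity become likely, below 4.5 aluminium
  toxicity).

State cross-tabs use a design-based proportional estimator: the area of a
cover is split across condition classes in proportion to its sample counts.
Change cross-tabs attribute each changed cell to its nearest sample.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .extent import ChangeMatrix
from .grids import NODATA, LandCoverGrid
from .nomenclature import SEEA_CODES

SOC_CLASSES = ("peat", "organo_mineral", "humus_mineral", "mineral")

#: pH bin labels, low to high.
PH_CLASSES = ("<4.5", "4.5-5", "5-6", "6-7", "7-8.3", ">8.3")
_PH_BREAKS = (4.5, 5.0, 6.0, 7.0, 8.3)

SOC_ORGANO_MINERAL_G_KG = 120.0  # 12 % SOC
SOC_HUMUS_MINERAL_G_KG = 30.0   # 3 % SOC
PEAT_PROBABILITY_THRESHOLD = 0.35


@dataclass(frozen=True)
class SoilSample:
    """One topsoil point record tied to a grid cell."""

    sample_id: str
    row: int
    col: int
    cover: int          # SEEA code
    soc: float          # g/kg
    ph: float
    peat: bool = False

    def __post_init__(self) -> None:
        if self.soc < 0:
            raise ValueError(f"sample {self.sample_id}: soc must be >= 0, got {self.soc}")
        if not (0 < self.ph < 14):
            raise ValueError(f"sample {self.sample_id}: pH must be in (0, 14), got {self.ph}")


def peat_mask(prob_grid: np.ndarray, threshold: float = PEAT_PROBABILITY_THRESHOLD) -> np.ndarray:
    """Boolean grid: True where peat probability strictly exceeds threshold."""
    prob = np.asarray(prob_grid, dtype=float)
    if (prob < 0).any() or (prob > 1).any():
        raise ValueError("peat probabilities must lie in [0, 1]")
    return prob > threshold


def classify_soc(sample: SoilSample) -> str:
    """SOC condition class of one sample; the peat flag takes precedence."""
    if sample.soc < 0:
        raise ValueError(f"soc must be >= 0, got {sample.soc}")
    if sample.peat:
        return "peat"
    if sample.soc > SOC_ORGANO_MINERAL_G_KG:
        return "organo_mineral"
    if sample.soc >= SOC_HUMUS_MINERAL_G_KG:
        return "humus_mineral"
    return "mineral"


def classify_ph(ph: float) -> str:
    """pH bin; lower-inclusive bins, with 8.3 itself falling in "7-8.3"."""
    if not (0 < ph < 14):
        raise ValueError(f"pH must be in (0, 14), got {ph}")
    if ph < 4.5:
        return "<4.5"
    if ph < 5.0:
        return "4.5-5"
    if ph < 6.0:
        return "5-6"
    if ph < 7.0:
        return "6-7"
    if ph <= 8.3:
        return "7-8.3"
    return ">8.3"


def _classify(sample: SoilSample, classifier: str) -> str:
    if classifier == "soc":
        return classify_soc(sample)
    if classifier == "ph":
        return classify_ph(sample.ph)
    raise ValueError(f"classifier must be 'soc' or 'ph', got {classifier!r}")


def _condition_labels(classifier: str) -> tuple[str, ...]:
    return SOC_CLASSES if classifier == "soc" else PH_CLASSES


def condition_crosstab(
    samples: list[SoilSample],
    cover_areas_ha: dict[int, float] | pd.Series,
    classifier: str = "soc",
) -> pd.DataFrame:
    """Design-based state cross-tab: cover rows x condition columns, area in ha.

    area(cover, class) = cover area x (samples of that cover in the class) /
    (samples of that cover); row sums therefore equal the cover areas exactly.
    """
    labels = _condition_labels(classifier)
    areas = pd.Series(cover_areas_ha, dtype=float)
    counts: dict[int, dict[str, int]] = {}
    for s in samples:
        counts.setdefault(s.cover, {k: 0 for k in labels})
        counts[s.cover][_classify(s, classifier)] += 1
    covers = [c for c in areas.index if areas[c] > 0]
    missing = [c for c in covers if c not in counts]
    if missing:
        raise ValueError(f"covers with area > 0 but no samples: {missing}")
    out = pd.DataFrame(0.0, index=covers, columns=list(labels))
    for c in covers:
        n = sum(counts[c].values())
        for k in labels:
            out.at[c, k] = areas[c] * counts[c][k] / n
    out.index.name = "seea_code"
    return out


def change_condition_crosstab(
    cm: ChangeMatrix,
    samples: list[SoilSample],
    grid_t0: LandCoverGrid,
    grid_t1: LandCoverGrid,
    classifier: str = "soc",
) -> pd.DataFrame:
    """Condition of land that changed cover, by (from, to, condition), area ha.

    Each changed cell takes the condition class of its nearest sample
    (Euclidean distance in grid coordinates; ties break to the lowest
    sample_id). The per-condition marginal is the "area of changed land in
    each condition class" view.
    """
    if not samples:
        raise ValueError("change_condition_crosstab requires at least one sample")
    if grid_t0.shape != grid_t1.shape:
        raise ValueError("grids must share shape")
    c0, c1 = grid_t0.codes, grid_t1.codes
    changed = (c0 != c1) & (c0 != NODATA) & (c1 != NODATA)
    labels = _condition_labels(classifier)
    cols = ["from_code", "to_code", "condition", "area_ha"]
    if not changed.any():
        return pd.DataFrame(columns=cols)

    ordered = sorted(samples, key=lambda s: s.sample_id)
    pts = np.array([(s.row, s.col) for s in ordered], dtype=float)
    classes = np.array([_classify(s, classifier) for s in ordered])
    rr, cc = np.nonzero(changed)
    cells = np.stack([rr, cc], axis=1).astype(float)
    # full distance matrix: argmin over samples sorted by id realises the
    # lowest-id tie-break deterministically
    d2 = ((cells[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    cell_ha = grid_t0.cell_area * 100.0  # km² -> ha

    agg: dict[tuple[int, int, str], float] = {}
    for i in range(len(rr)):
        key = (int(c0[rr[i], cc[i]]), int(c1[rr[i], cc[i]]), str(classes[nearest[i]]))
        agg[key] = agg.get(key, 0.0) + cell_ha
    rows = [(f, t, k, a) for (f, t, k), a in sorted(agg.items(), key=lambda kv: (kv[0][0], kv[0][1], labels.index(kv[0][2])))]
    return pd.DataFrame(rows, columns=cols)


# --- sample CSV I/O ---------------------------------------------------------

SAMPLE_COLUMNS = ("sample_id", "row", "col", "cover", "soc_g_per_kg", "ph", "peat")


def write_samples_csv(samples: list[SoilSample], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SAMPLE_COLUMNS)
        for s in samples:
            w.writerow([s.sample_id, s.row, s.col, s.cover, repr(s.soc), repr(s.ph), int(s.peat)])


def read_samples_csv(path: str | Path) -> list[SoilSample]:
    out: list[SoilSample] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            out.append(
                SoilSample(
                    sample_id=rec["sample_id"],
                    row=int(rec["row"]),
                    col=int(rec["col"]),
                    cover=int(rec["cover"]),
                    soc=float(rec["soc_g_per_kg"]),
                    ph=float(rec["ph"]),
                    peat=bool(int(rec["peat"])),
                )
            )
    return out
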
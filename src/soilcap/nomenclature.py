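"""SEEA land-cover nomenclature and the CORINE aggregation mapping.

The UN SEEA interim land-cover classification distinguishes 14 classes.
European CORINE Land Cover (CLC) grids use a 44-class, 3-digit nomenclature;
for SEEA accounting each CLC code is aggregated to exactly one SEEA class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

#: SEEA interim classification: code -> class name.
SEEA_CLASSES: dict[int, str] = {
    1: "Artificial surfaces",
    2: "Herbaceous crops",
    3: "Woody crops",
    4: "Multiple or layered crops",
    5: "Grassland",
    6: "Tree covered areas",
    7: "Mangrove",
    8: "Shrub covered areas",
    9: "Shrubs and/or herbaceous vegetation, aquatic or regularly flooded",
    10: "Sparsely natural vegetated areas",
    11: "Terrestrial barren land",
    12: "Permanent snow and glaciers",
    13: "Inland water bodies",
    14: "Coastal water bodies and intertidal areas",
}

SEEA_CODES: tuple[int, ...] = tuple(SEEA_CLASSES)

#: Default CLC (3-digit) -> SEEA aggregation. 1x -> artificial, 21x -> herbaceous
#: crops, 22x -> woody crops, 24x -> heterogeneous agriculture, pastures (231)
#: and natural grassland (321) -> grassland, forests (31x) and transitional
#: woodland-shrub (324) -> tree covered, moors/sclerophyllous (322, 323) ->
#: shrub covered, inland wetlands (41x) -> aquatic/regularly flooded vegetation,
#: sparse vegetation (333) -> sparsely vegetated, beaches/rock/burnt (331, 332,
#: 334) -> barren, glaciers (335) -> snow and ice, inland water (51x) -> inland
#: water bodies, coastal wetlands and marine water (42x, 52x) -> coastal water.
#: No CLC class maps to SEEA 7 (Mangrove) in Europe.
CORINE_TO_SEEA: dict[int, int] = {
    # 1xx artificial surfaces
    111: 1, 112: 1, 121: 1, 122: 1, 123: 1, 124: 1,
    131: 1, 132: 1, 133: 1, 141: 1, 142: 1,
    # 21x arable
    211: 2, 212: 2, 213: 2,
    # 22x permanent crops
    221: 3, 222: 3, 223: 3,
    # 24x heterogeneous agricultural
    241: 4, 242: 4, 243: 4, 244: 4,
    # pastures + natural grassland
    231: 5, 321: 5,
    # forests + transitional woodland-shrub
    311: 6, 312: 6, 313: 6, 324: 6,
    # moors/heathland + sclerophyllous
    322: 8, 323: 8,
    # inland wetlands
    411: 9, 412: 9,
    # sparsely vegetated
    333: 10,
    # beaches/dunes, bare rock, burnt
    331: 11, 332: 11, 334: 11,
    # glaciers and perpetual snow
    335: 12,
    # inland waters
    511: 13, 512: 13,
    # coastal wetlands + marine waters
    421: 14, 422: 14, 423: 14, 521: 14, 522: 14, 523: 14,
}

assert len(CORINE_TO_SEEA) == 44


@dataclass(frozen=True)
class ClassMapping:
    """A total mapping from CORINE 3-digit codes to SEEA codes 1-14."""

    entries: dict[int, int]

    def __post_init__(self) -> None:
        bad = {c: s for c, s in self.entries.items() if s not in SEEA_CLASSES}
        if bad:
            raise ValueError(f"mapping targets outside SEEA codes 1-14: {bad}")

    def __getitem__(self, corine_code: int) -> int:
        return self.entries[corine_code]

    def __contains__(self, corine_code: int) -> bool:
        return corine_code in self.entries

    @classmethod
    def default(cls) -> "ClassMapping":
        return cls(dict(CORINE_TO_SEEA))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClassMapping":
        """Read a two-column CSV (corine_code, seea_code); header optional."""
        entries: dict[int, int] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                try:
                    corine, seea = int(row[0]), int(row[1])
                except ValueError:
                    continue  # header line
                entries[corine] = seea
        if not entries:
            raise ValueError(f"no mapping entries found in {path}")
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["corine_code", "seea_code"])
            for corine in sorted(self.entries):
                writer.writerow([corine, self.entries[corine]])


def default_mapping_path() -> Path:
    """Path of the packaged default CORINE->SEEA mapping CSV."""
    return Path(str(resources.files("soilcap").joinpath("fixtures/corine_to_seea.csv")))
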
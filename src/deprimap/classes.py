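"""Land-cover class codes and groupings.

The classification scheme distinguishes nine cover types at 30 m nominal
resolution: four built ("impervious") classes — corrugated roofs,
white-painted roofs, tile roofs and pavement — plus water, vegetation,
sand, exposed soil and cloud. Corrugated steel roofing is the cheap
material typical of informal settlements, while tile and white-painted
roofs mark higher-income residential and commercial buildings, so the
impervious composition of a neighbourhood carries socioeconomic signal.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

NODATA: int = 0


class LandCover(IntEnum):
    """Integer codes used in categorical land-cover grids (0 = nodata)."""

    CORRUGATED = 1
    WHITE_PAINTED = 2
    TILE = 3
    PAVEMENT = 4
    WATER = 5
    VEGETATION = 6
    SAND = 7
    EXPOSED_SOIL = 8
    CLOUD = 9


#: Built classes; the denominator of composition percentages and the urban mask.
IMPERVIOUS_CLASSES: tuple[LandCover, ...] = (
    LandCover.CORRUGATED,
    LandCover.WHITE_PAINTED,
    LandCover.TILE,
    LandCover.PAVEMENT,
)

#: Order of the land-cover feature variables (CO, WP, TR, PA, TX).
LANDCOVER_FEATURES: tuple[str, ...] = ("CO", "WP", "TR", "PA", "TX")

#: Order of the socioeconomic variables (bathroom, water, garbage, income, crowding).
SOCIO_FEATURES: tuple[str, ...] = ("BA", "WA", "GA", "IN", "CR")

ALL_CODES = frozenset(int(c) for c in LandCover)


def validate_landcover(grid: np.ndarray) -> None:
    """Raise ``ValueError`` if *grid* holds codes outside the 9-class scheme."""
    codes = np.unique(grid)
    bad = [int(c) for c in codes if int(c) != NODATA and int(c) not in ALL_CODES]
    if bad:
        raise ValueError(f"unknown land-cover codes {bad}; expected 1..9 or 0 (nodata)")


def is_impervious(grid: np.ndarray) -> np.ndarray:
    """Boolean grid marking the built classes (roofs and pavement)."""
    return np.isin(grid, [int(c) for c in IMPERVIOUS_CLASSES])
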
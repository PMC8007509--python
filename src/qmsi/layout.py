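"""Mimetic tissue array layouts.

The calibration device is a gelatin block cast from a 3D-printed mold whose
lid carries 15 square pillars; each pillar leaves a well that is filled with
drug-spiked tissue homogenate.  The default geometry is a 20 × 20 mm block
with 3 × 3 mm wells at 2 mm spacing (a 4 × 4 position grid with one corner
left empty as an orientation marker).  Wells are filled in randomized order
to avoid leverage of the high calibration levels on one side of the block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LayoutError
from .grid import ANALYTE, DEFAULT_CHANNELS, RoiMask

ROLE_CALIBRATION = "calibration"
ROLE_BLANK = "blank"
ROLE_QC = "qc"
_ROLES = (ROLE_CALIBRATION, ROLE_BLANK, ROLE_QC)

#: Spiked homogenate concentration ladder, µg drug per g tissue.
DEFAULT_LADDER: tuple[float, ...] = (12.5, 25.0, 50.0, 125.0, 250.0, 500.0, 1250.0, 2500.0)
#: Quality-control levels, µg/g.
DEFAULT_QC_LEVELS: tuple[float, ...] = (25.0, 1250.0)


@dataclass(frozen=True)
class Well:
    """One filled well: a half-open pixel rectangle with a role and nominal levels.

    ``nominal_conc`` maps analyte channel name → spiked concentration in µg/g.
    The rectangle covers [x0, x0+width) × [y0, y0+height) in grid pixels.
    """

    well_id: str
    role: str
    nominal_conc: dict[str, float]
    replicate_id: int
    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise LayoutError(f"well {self.well_id!r}: unknown role {self.role!r}")
        if self.width < 1 or self.height < 1:
            raise LayoutError(f"well {self.well_id!r}: non-positive extent")
        for ch, c in self.nominal_conc.items():
            if not np.isfinite(c) or c < 0:
                raise LayoutError(f"well {self.well_id!r}: bad nominal {c} for {ch}")
            if self.role == ROLE_BLANK and c != 0:
                raise LayoutError(f"blank well {self.well_id!r} has nonzero nominal for {ch}")
            if self.role == ROLE_CALIBRATION and c <= 0:
                raise LayoutError(
                    f"calibration well {self.well_id!r} has non-positive nominal for {ch}"
                )

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    def mask(self) -> RoiMask:
        return RoiMask.from_rect(self.well_id, self.x0, self.y0, self.width, self.height)

    def strip_masks(self, n: int = 3) -> list[RoiMask]:
        """Split the well into ``n`` disjoint vertical strips (replicate sub-ROIs)."""
        if not 1 <= n <= self.width:
            raise LayoutError(f"well {self.well_id!r}: cannot cut {n} strips from width {self.width}")
        edges = np.linspace(0, self.width, n + 1).round().astype(int)
        return [
            RoiMask.from_rect(
                f"{self.well_id}_r{k + 1}",
                self.x0 + int(edges[k]),
                self.y0,
                int(edges[k + 1] - edges[k]),
                self.height,
            )
            for k in range(n)
        ]

    def overlaps(self, other: "Well") -> bool:
        return not (
            self.x0 + self.width <= other.x0
            or other.x0 + other.width <= self.x0
            or self.y0 + self.height <= other.y0
            or other.y0 + other.height <= self.y0
        )


@dataclass
class ArrayLayout:
    """Well geometry and roles for one mimetic array, plus the raster extent."""

    grid_width: int
    grid_height: int
    wells: list[Well] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise LayoutError(f"duplicate well ids: {ids}")
        for w in self.wells:
            if w.x0 < 0 or w.y0 < 0 or w.x0 + w.width > self.grid_width or w.y0 + w.height > self.grid_height:
                raise LayoutError(
                    f"well {w.well_id!r} extends outside the "
                    f"{self.grid_width}x{self.grid_height} grid"
                )
        for i, a in enumerate(self.wells):
            for b in self.wells[i + 1 :]:
                if a.overlaps(b):
                    raise LayoutError(f"wells {a.well_id!r} and {b.well_id!r} overlap")

    def by_role(self, role: str) -> list[Well]:
        return [w for w in self.wells if w.role == role]

    @property
    def analyte_channels(self) -> list[str]:
        names: list[str] = []
        for w in self.wells:
            for ch in w.nominal_conc:
                if ch not in names:
                    names.append(ch)
        return names

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) half-open bounding box of all wells."""
        if not self.wells:
            raise LayoutError("layout has no wells")
        x0 = min(w.x0 for w in self.wells)
        y0 = min(w.y0 for w in self.wells)
        x1 = max(w.x0 + w.width for w in self.wells)
        y1 = max(w.y0 + w.height for w in self.wells)
        return x0, y0, x1, y1


def default_mimetic_layout(
    *,
    pixel_size_um: float = 100.0,
    analyte_channels: tuple[str, ...] | None = None,
    ladder: tuple[float, ...] = DEFAULT_LADDER,
    qc_levels: tuple[float, ...] = DEFAULT_QC_LEVELS,
    n_blanks: int = 3,
    block_mm: float = 20.0,
    well_mm: float = 3.0,
    spacing_mm: float = 2.0,
    seed: int | None = 0,
) -> ArrayLayout:
    """Build the default 15-position mimetic array.

    The 4 × 4 position grid drops its bottom-right corner (the empty
    orientation marker), leaving 15 positions.  The samples — the ladder
    levels, ``n_blanks`` blanks, and one well per QC level — are assigned to
    positions in a seeded random permutation; surplus positions stay
    unfilled.  With ``seed=None`` the fill order is the natural one.
    """
    if analyte_channels is None:
        analyte_channels = tuple(c.name for c in DEFAULT_CHANNELS if c.kind == ANALYTE)
    if sorted(ladder) != list(ladder) or len(set(ladder)) != len(ladder) or min(ladder) <= 0:
        raise LayoutError(f"ladder must be strictly increasing and positive: {ladder}")

    px_per_mm = 1000.0 / pixel_size_um
    grid_px = int(round(block_mm * px_per_mm))
    well_px = int(round(well_mm * px_per_mm))
    pitch_px = int(round((well_mm + spacing_mm) * px_per_mm))
    n_side = 4
    margin_px = (grid_px - ((n_side - 1) * pitch_px + well_px)) // 2
    if margin_px < 0:
        raise LayoutError("wells do not fit inside the block at this pixel size")

    positions = [
        (row, col)
        for row in range(n_side)
        for col in range(n_side)
        if not (row == n_side - 1 and col == n_side - 1)  # empty orientation corner
    ]

    samples: list[tuple[str, str, dict[str, float]]] = []
    for i, conc in enumerate(ladder, start=1):
        samples.append((f"C{i}", ROLE_CALIBRATION, {ch: float(conc) for ch in analyte_channels}))
    for i in range(1, n_blanks + 1):
        samples.append((f"BLK{i}", ROLE_BLANK, {ch: 0.0 for ch in analyte_channels}))
    for conc in qc_levels:
        samples.append((f"QC{conc:g}", ROLE_QC, {ch: float(conc) for ch in analyte_channels}))
    if len(samples) > len(positions):
        raise LayoutError(f"{len(samples)} samples exceed {len(positions)} available positions")

    order = np.arange(len(positions))
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(positions))

    wells = []
    for (well_id, role, nominal), pos_idx in zip(samples, order):
        row, col = positions[int(pos_idx)]
        replicate = int(well_id[3:]) if role == ROLE_BLANK else 1
        wells.append(
            Well(
                well_id=well_id,
                role=role,
                nominal_conc=nominal,
                replicate_id=replicate,
                x0=margin_px + col * pitch_px,
                y0=margin_px + row * pitch_px,
                width=well_px,
                height=well_px,
            )
        )
    return ArrayLayout(grid_width=grid_px, grid_height=grid_px, wells=wells)
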
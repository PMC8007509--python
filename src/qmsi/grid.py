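"""In-memory containers for multi-channel MSI rasters and ROI masks.

A :class:`ChannelGrid` holds one already-integrated intensity image per MRM
channel (one precursor→fragment transition per channel) on a shared
rectangular raster.  The coordinate convention is image-style: ``(0, 0)`` is
the top-left pixel, ``x`` grows rightward along columns and ``y`` grows
downward along rows.  Intensity arrays are indexed ``[y, x]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import GridFormatError, RoiError

#: Reserved channel name under which per-pixel cell densities travel when a
#: cell-density map reuses the ChannelGrid container.
CELL_DENSITY_CHANNEL = "cell_density"

ANALYTE = "analyte"
REFERENCE = "reference"


@dataclass(frozen=True)
class ChannelDef:
    """One acquired MRM channel.

    Parameters
    ----------
    name
        Unique channel name (e.g. ``"compound_A"``).
    kind
        ``"analyte"`` for drug channels, ``"reference"`` for the endogenous
        normalization channel (here a phospholipid transition).
    mrm_precursor_mz, mrm_fragment_mz
        Optional m/z metadata for the monitored transition.
    """

    name: str
    kind: str = ANALYTE
    mrm_precursor_mz: float | None = None
    mrm_fragment_mz: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (ANALYTE, REFERENCE):
            raise GridFormatError(
                f"channel {self.name!r}: kind must be 'analyte' or 'reference', got {self.kind!r}"
            )


#: Default channel set mirroring a two-drug DESI-MRM acquisition with an
#: endogenous phosphatidylcholine reference (m/z 782.6 → 184.1).
DEFAULT_CHANNELS: tuple[ChannelDef, ...] = (
    ChannelDef("compound_A", ANALYTE, 502.0, 84.0),
    ChannelDef("compound_B", ANALYTE, 516.0, 98.0),
    ChannelDef("lipid_782", REFERENCE, 782.6, 184.1),
)


@dataclass
class ChannelGrid:
    """Per-pixel intensities for named MRM channels on a rectangular raster."""

    pixel_size_um: float
    channels: list[ChannelDef]
    intensities: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise GridFormatError(f"duplicate channel names: {names}")
        if set(self.intensities) != set(names):
            raise GridFormatError(
                f"intensity arrays {sorted(self.intensities)} do not match "
                f"declared channels {sorted(names)}"
            )
        if not (self.pixel_size_um > 0 and math.isfinite(self.pixel_size_um)):
            raise GridFormatError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        shapes = {self.intensities[n].shape for n in names}
        if len(shapes) != 1:
            raise GridFormatError(f"channels disagree on grid shape: {shapes}")
        (shape,) = shapes
        if len(shape) != 2 or shape[0] < 1 or shape[1] < 1:
            raise GridFormatError(f"intensity arrays must be 2-D and non-empty, got shape {shape}")
        for name in names:
            arr = np.asarray(self.intensities[name], dtype=float)
            if not np.all(np.isfinite(arr)):
                raise GridFormatError(f"channel {name!r} contains NaN or infinite intensities")
            if np.any(arr < 0):
                raise GridFormatError(f"channel {name!r} contains negative intensities")
            self.intensities[name] = arr

    @property
    def height(self) -> int:
        return next(iter(self.intensities.values())).shape[0]

    @property
    def width(self) -> int:
        return next(iter(self.intensities.values())).shape[1]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_def(self, name: str) -> ChannelDef:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.intensities[name]


@dataclass(frozen=True)
class RoiMask:
    """A named set of ``(x, y)`` pixel coordinates on the MSI raster."""

    name: str
    pixels: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.pixels:
            raise RoiError(f"ROI {self.name!r} is empty")
        object.__setattr__(self, "pixels", frozenset((int(x), int(y)) for x, y in self.pixels))

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(ys, xs)`` index arrays in deterministic (y, x) order."""
        pts = sorted((y, x) for x, y in self.pixels)
        ys = np.fromiter((p[0] for p in pts), dtype=int, count=len(pts))
        xs = np.fromiter((p[1] for p in pts), dtype=int, count=len(pts))
        return ys, xs

    def check_bounds(self, grid: ChannelGrid) -> None:
        for x, y in self.pixels:
            if not (0 <= x < grid.width and 0 <= y < grid.height):
                raise RoiError(
                    f"ROI {self.name!r}: pixel ({x}, {y}) outside "
                    f"{grid.width}x{grid.height} grid"
                )

    @classmethod
    def from_rect(cls, name: str, x0: int, y0: int, width: int, height: int) -> "RoiMask":
        """Half-open rectangle [x0, x0+width) × [y0, y0+height)."""
        return cls(name, frozenset((x, y) for x in range(x0, x0 + width) for y in range(y0, y0 + height)))

    @classmethod
    def from_indices(cls, name: str, ys: Iterable[int], xs: Iterable[int]) -> "RoiMask":
        return cls(name, frozenset(zip((int(x) for x in xs), (int(y) for y in ys))))
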
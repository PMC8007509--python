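"""Synthetic DESI-MRM data with known ground truth.

Generative model
----------------
Channels are already-integrated MRM transition intensities; no mass spectra
are simulated.  Each pixel carries an intact-cell density ``d`` (cells per
pixel).  Expected intensities are

* reference (endogenous lipid):  ``lipid_gain · d``
* analyte at concentration ``c`` µg/g with response slope ``s`` (ratio units
  per µg/g):  ``s · c · lipid_gain · d² / d_cal``

where ``d_cal`` is the homogenate cell density of the calibration wells.  In
a calibration well (``d = d_cal``) the expected analyte/lipid ratio of sums
is therefore exactly ``s · c``; in tissue whose intact-cell density differs
from the homogenate, the raw ratio scales with ``d / d_cal`` and the
cell-count correction of :func:`qmsi.roi_quant.cell_corrected_ratio` undoes
that factor.  This encodes the observation that the lipid reference tracks
intact-cell density while the drug content per gram of tissue does not.

Pixel-to-pixel variability is a *shared* multiplicative log-normal field
(unit mean, coefficient of variation ``pixel_rsd``, matching the ~20 %
pixel-to-pixel RSD seen for the lipid channel in liver sections) that
multiplies every tissue-derived channel of a pixel: it models desorption
efficiency and tissue ion suppression, which act on analyte and reference
alike — the reason the analyte/lipid ratio normalization works.  Each
channel additionally receives an independent half-normal chemical baseline
(scale ``baseline_noise_sd``): intensities are counts and never negative,
and the baseline's positive mean is the same at every pixel, so the
calibration intercept absorbs it.  Inter-well diffusion of analyte and tissue
material into the gelatin corridor is modelled as a Gaussian blur
(``diffusion_sigma_mm``) of the expected concentration and cell-density
fields before noise is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigError
from .grid import (
    ANALYTE,
    CELL_DENSITY_CHANNEL,
    DEFAULT_CHANNELS,
    REFERENCE,
    ChannelDef,
    ChannelGrid,
    RoiMask,
)
from .layout import ArrayLayout

BACKGROUND = "background"


def _default_slopes() -> dict[str, float]:
    return {c.name: 0.001 for c in DEFAULT_CHANNELS if c.kind == ANALYTE}


@dataclass
class SimParams:
    """Parameters of the synthetic DESI-MRM acquisition.

    Attributes
    ----------
    response_slope_per_channel
        Analyte channel name → expected (analyte/lipid) ratio per µg/g.
    lipid_gain
        Reference-channel counts per cell-density unit.
    pixel_rsd
        Pixel-to-pixel relative standard deviation of the multiplicative
        noise (fraction; 0.2 ≈ the RSD observed for m/z 782 in liver).
    baseline_noise_sd
        Scale of the additive half-normal baseline, counts.
    diffusion_sigma_mm
        Gaussian diffusion length of homogenate material into gelatin.
    pixel_size_um
        Raster pixel edge length.
    homogenate_cell_density
        Intact-cell density of the calibration homogenate, cells/pixel.
    seed
        RNG seed; a fixed seed reproduces grids bit-for-bit.
    """

    response_slope_per_channel: dict[str, float] = field(default_factory=_default_slopes)
    lipid_gain: float = 100.0
    pixel_rsd: float = 0.2
    baseline_noise_sd: float = 5.0
    diffusion_sigma_mm: float = 0.0
    pixel_size_um: float = 100.0
    homogenate_cell_density: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.response_slope_per_channel:
            raise ConfigError("at least one analyte channel slope is required")
        for ch, s in self.response_slope_per_channel.items():
            if not (s > 0 and math.isfinite(s)):
                raise ConfigError(f"response slope for {ch!r} must be > 0, got {s}")
        if not self.lipid_gain > 0:
            raise ConfigError(f"lipid_gain must be > 0, got {self.lipid_gain}")
        if not 0 <= self.pixel_rsd < 1:
            raise ConfigError(f"pixel_rsd must be in [0, 1), got {self.pixel_rsd}")
        if self.baseline_noise_sd < 0:
            raise ConfigError("baseline_noise_sd must be >= 0")
        if self.diffusion_sigma_mm < 0:
            raise ConfigError("diffusion_sigma_mm must be >= 0")
        if not self.pixel_size_um > 0:
            raise ConfigError("pixel_size_um must be > 0")
        if not self.homogenate_cell_density > 0:
            raise ConfigError("homogenate_cell_density must be > 0")

    @property
    def sigma_px(self) -> float:
        return self.diffusion_sigma_mm * 1000.0 / self.pixel_size_um

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=int(seed))


@dataclass
class RegionMap:
    """Per-pixel region labels and per-region nominal concentrations.

    ``labels`` is a (height, width) array of region-name strings; pixels not
    covered by tissue carry :data:`BACKGROUND`.  ``region_concentrations``
    maps each non-background region to {channel → µg/g}.
    """

    labels: np.ndarray
    region_concentrations: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ConfigError("labels must be a 2-D array of region names")
        present = {str(r) for r in np.unique(self.labels)} - {BACKGROUND}
        declared = set(self.region_concentrations)
        if declared - present:
            raise ConfigError(
                f"region_concentrations names unknown regions: {sorted(declared - present)}"
            )
        if present - declared:
            raise ConfigError(
                f"regions without concentrations: {sorted(present - declared)}"
            )
        for region, per_ch in self.region_concentrations.items():
            for ch, c in per_ch.items():
                if not (np.isfinite(c) and c >= 0):
                    raise ConfigError(f"region {region!r}: bad concentration {c} for {ch}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def regions(self) -> list[str]:
        return sorted(self.region_concentrations)

    def region_mask(self, region: str) -> np.ndarray:
        return self.labels == region

    def region_roi(self, region: str) -> RoiMask:
        ys, xs = np.nonzero(self.region_mask(region))
        return RoiMask.from_indices(region, ys, xs)


def _channel_defs(analyte_names: list[str], reference_channel: str) -> list[ChannelDef]:
    known = {c.name: c for c in DEFAULT_CHANNELS}
    defs = [known.get(n, ChannelDef(n, ANALYTE)) for n in analyte_names]
    defs.append(known.get(reference_channel, ChannelDef(reference_channel, REFERENCE)))
    return defs


def _suppression_field(
    shape: tuple[int, int], params: SimParams, rng: np.random.Generator
) -> np.ndarray:
    """Shared per-pixel desorption/ion-suppression factor (unit-mean log-normal)."""
    if params.pixel_rsd == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(params.pixel_rsd**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=shape))


def _baseline(expected: np.ndarray, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    # half-normal chemical background: nonnegative, same positive mean at every
    # pixel, so the calibration intercept absorbs it and blanks read ~0
    if params.baseline_noise_sd > 0:
        expected = expected + np.abs(rng.normal(0.0, params.baseline_noise_sd, size=expected.shape))
    return expected


def _generate_channels(
    conc_fields: dict[str, np.ndarray],
    density: np.ndarray,
    params: SimParams,
    reference_channel: str,
    rng: np.random.Generator,
) -> ChannelGrid:
    d_cal = params.homogenate_cell_density
    suppression = _suppression_field(density.shape, params, rng)
    intensities: dict[str, np.ndarray] = {}
    for ch in conc_fields:  # deterministic draw order: analytes first, then reference
        slope = params.response_slope_per_channel[ch]
        expected = slope * conc_fields[ch] * params.lipid_gain * density**2 / d_cal
        intensities[ch] = _baseline(expected * suppression, params, rng)
    intensities[reference_channel] = _baseline(
        params.lipid_gain * density * suppression, params, rng
    )
    return ChannelGrid(
        pixel_size_um=params.pixel_size_um,
        channels=_channel_defs(list(conc_fields), reference_channel),
        intensities=intensities,
    )


def generate_mimetic_array(
    layout: ArrayLayout,
    params: SimParams,
    reference_channel: str = "lipid_782",
) -> tuple[ChannelGrid, pd.DataFrame]:
    """Simulate one cryosection of a spiked mimetic tissue array.

    Returns the channel grid and a per-well truth table with columns
    ``well_id, role, channel, nominal_conc_ug_g``.
    """
    analytes = layout.analyte_channels
    missing = [ch for ch in analytes if ch not in params.response_slope_per_channel]
    if missing:
        raise ConfigError(f"no response slope for layout channels: {missing}")

    shape = (layout.grid_height, layout.grid_width)
    conc_fields = {ch: np.zeros(shape) for ch in analytes}
    density = np.zeros(shape)
    for w in layout.wells:
        sl = (slice(w.y0, w.y0 + w.height), slice(w.x0, w.x0 + w.width))
        density[sl] = params.homogenate_cell_density
        for ch, conc in w.nominal_conc.items():
            conc_fields[ch][sl] = conc
    if params.sigma_px > 0:
        density = gaussian_filter(density, params.sigma_px)
        conc_fields = {ch: gaussian_filter(f, params.sigma_px) for ch, f in conc_fields.items()}

    rng = np.random.default_rng(params.seed)
    grid = _generate_channels(conc_fields, density, params, reference_channel, rng)

    truth = pd.DataFrame(
        [
            {
                "well_id": w.well_id,
                "role": w.role,
                "channel": ch,
                "nominal_conc_ug_g": conc,
            }
            for w in layout.wells
            for ch, conc in w.nominal_conc.items()
        ]
    )
    return grid, truth


def generate_dosed_section(
    region_map: RegionMap,
    params: SimParams,
    cell_density_map: np.ndarray | None = None,
    reference_channel: str = "lipid_782",
) -> tuple[ChannelGrid, ChannelGrid, dict[str, dict[str, float]]]:
    """Simulate a dosed tissue section with labelled regions.

    Returns ``(grid, cell_density_grid, truth)`` where ``truth`` is the
    region → channel → µg/g mapping and the cell-density grid reuses the
    ChannelGrid container under the reserved ``cell_density`` channel.
    Background pixels carry baseline noise only.
    """
    shape = region_map.shape
    if cell_density_map is None:
        cell_density_map = np.where(
            region_map.labels != BACKGROUND, params.homogenate_cell_density, 0.0
        )
    cell_density_map = np.asarray(cell_density_map, dtype=float)
    if cell_density_map.shape != shape:
        raise ConfigError(
            f"cell density map shape {cell_density_map.shape} != region map shape {shape}"
        )

    analytes = sorted({ch for per in region_map.region_concentrations.values() for ch in per})
    missing = [ch for ch in analytes if ch not in params.response_slope_per_channel]
    if missing:
        raise ConfigError(f"no response slope for section channels: {missing}")

    conc_fields = {ch: np.zeros(shape) for ch in analytes}
    for region, per_ch in region_map.region_concentrations.items():
        mask = region_map.region_mask(region)
        for ch, conc in per_ch.items():
            conc_fields[ch][mask] = conc
    density = cell_density_map.copy()
    if params.sigma_px > 0:
        density = gaussian_filter(density, params.sigma_px)
        conc_fields = {ch: gaussian_filter(f, params.sigma_px) for ch, f in conc_fields.items()}

    rng = np.random.default_rng(params.seed)
    grid = _generate_channels(conc_fields, density, params, reference_channel, rng)
    density_grid = ChannelGrid(
        pixel_size_um=params.pixel_size_um,
        channels=[ChannelDef(CELL_DENSITY_CHANNEL, REFERENCE)],
        intensities={CELL_DENSITY_CHANNEL: cell_density_map.copy()},
    )
    truth = {r: dict(per) for r, per in region_map.region_concentrations.items()}
    return grid, density_grid, truth


def demo_region_map(
    height: int = 80,
    width: int = 80,
    region_concentrations: dict[str, dict[str, float]] | None = None,
    analyte_channels: tuple[str, ...] = ("compound_A",),
) -> RegionMap:
    """A liver-section-like label map: lesion blob, connective band, parenchyma.

    The outer 4-pixel frame is background (glass); a circular lesion sits in
    the upper-left of the tissue, a vertical connective-tissue band crosses
    the middle, and the remainder is parenchyma.
    """
    labels = np.full((height, width), BACKGROUND, dtype="U16")
    labels[4 : height - 4, 4 : width - 4] = "parenchyma"
    band_x0 = width // 2 - max(2, width // 16)
    band_x1 = width // 2 + max(2, width // 16)
    labels[4 : height - 4, band_x0:band_x1] = "connective"
    yy, xx = np.mgrid[0:height, 0:width]
    r = max(4, min(height, width) // 8)
    lesion = (yy - height // 4) ** 2 + (xx - width // 4) ** 2 <= r**2
    labels[lesion & (labels != BACKGROUND)] = "lesion"
    if region_concentrations is None:
        region_concentrations = {
            "lesion": {ch: 500.0 for ch in analyte_channels},
            "connective": {ch: 75.0 for ch in analyte_channels},
            "parenchyma": {ch: 240.0 for ch in analyte_channels},
        }
    return RegionMap(labels=labels, region_concentrations=region_concentrations)


def region_replicate_masks(region_map: RegionMap, region: str, n: int = 3) -> list[RoiMask]:
    """Split a region's pixels into ``n`` disjoint replicate ROIs.

    Pixels are interleaved in raster order so replicates sample the whole
    region, mirroring triplicate ROI extraction from one section.
    """
    ys, xs = np.nonzero(region_map.region_mask(region))
    if len(ys) < n:
        raise ConfigError(f"region {region!r} has {len(ys)} pixels, fewer than {n} replicates")
    return [
        RoiMask.from_indices(f"{region}_r{k + 1}", ys[k::n], xs[k::n]) for k in range(n)
    ]
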
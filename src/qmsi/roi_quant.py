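"""Regional quantification of dosed tissue sections.

Histology-drawn ROIs (lesion, connective tissue/blood vessel, parenchyma)
are registered onto the MSI raster, their summed analyte/lipid ratios are
corrected for the intact-cell density seen by the histology software, and
concentrations are back-calculated through the mimetic-array calibration
curve.  Reporting utilities compute pairwise fold differences between
regions/samples and concordance of parenchyma concentrations with LC-MS
ranges of whole-tissue homogenates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .calibration import (
    FLAG_ABOVE_ULOQ,
    FLAG_BELOW_LLOQ,
    FLAG_BELOW_LOD,
    FLAG_ND,
    FLAG_OK,
    CalibrationCurve,
    back_calculate,
    summed_ratio,
)
from .errors import ConcordanceError, GeometryError, RoiError
from .grid import CELL_DENSITY_CHANNEL, ChannelGrid, RoiMask
from .layout import ArrayLayout

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegistrationTransform:
    """Affine 2×3 map from ROI-source (histology) to MSI pixel coordinates.

    Maps column vectors: ``(x', y')ᵀ = A·(x, y)ᵀ + b`` with ``A`` the left
    2×2 block and ``b`` the last column.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise RoiError(f"registration matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise RoiError("registration transform has a singular linear part")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "RegistrationTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "RegistrationTransform":
        return cls(np.array([[1.0, 0.0, dx], [0.0, 1.0, dy]]))

    @classmethod
    def scaling(cls, sx: float, sy: float | None = None) -> "RegistrationTransform":
        sy = sx if sy is None else sy
        return cls(np.array([[sx, 0.0, 0.0], [0.0, sy, 0.0]]))

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return xy @ self.matrix[:, :2].T + self.matrix[:, 2]


@dataclass(frozen=True)
class RoiQuantResult:
    """Quantification of one ROI (over its replicate masks)."""

    roi_name: str
    n_pixels: int
    cell_count: float
    raw_ratio: float | None
    corrected_ratio: float | None
    conc: float | None
    flag: str
    conc_sd: float | None
    n_replicates: int
    replicate_concs: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "roi": self.roi_name,
            "n_pixels": self.n_pixels,
            "cell_count": self.cell_count,
            "raw_ratio": self.raw_ratio,
            "corrected_ratio": self.corrected_ratio,
            "conc_ug_g": self.conc,
            "conc_sd_ug_g": self.conc_sd,
            "n": self.n_replicates,
            "flag": self.flag,
        }


@dataclass(frozen=True)
class LcmsRange:
    """A confidential LC-MS result reported only as a concentration range."""

    sample_id: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low <= self.high:
            raise ConcordanceError(
                f"LC-MS range for {self.sample_id!r} must satisfy 0 < low <= high, "
                f"got [{self.low}, {self.high}]"
            )


def register_and_extract(
    grid: ChannelGrid, mask: RoiMask, transform: RegistrationTransform
) -> RoiMask:
    """Map an ROI into MSI pixel space (nearest-neighbor, de-duplicated).

    Source pixels are mapped through the affine transform, rounded to the
    nearest MSI pixel, and de-duplicated; pixels landing outside the grid
    are dropped with a logged count.  No intensity interpolation is done —
    MRM counts are per-pixel integrals.
    """
    xy = np.array(sorted(mask.pixels))
    mapped = np.rint(transform.apply(xy)).astype(int)
    inside = (
        (mapped[:, 0] >= 0)
        & (mapped[:, 0] < grid.width)
        & (mapped[:, 1] >= 0)
        & (mapped[:, 1] < grid.height)
    )
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.warning("ROI %r: %d mapped pixels fall outside the grid", mask.name, n_dropped)
    kept = mapped[inside]
    if kept.size == 0:
        raise RoiError(f"ROI {mask.name!r}: empty after registration and clipping")
    pixels = frozenset((int(x), int(y)) for x, y in kept)
    if len(pixels) < len(kept):
        logger.info(
            "ROI %r: %d source pixels collapsed to %d MSI pixels",
            mask.name,
            len(kept),
            len(pixels),
        )
    return RoiMask(mask.name, pixels)


def _density_array(cell_density_map: ChannelGrid | np.ndarray) -> np.ndarray:
    if isinstance(cell_density_map, ChannelGrid):
        return cell_density_map[CELL_DENSITY_CHANNEL]
    return np.asarray(cell_density_map, dtype=float)


def roi_cell_stats(
    pixels: RoiMask, cell_density_map: ChannelGrid | np.ndarray
) -> tuple[float, float]:
    """Return (total cell count, mean cells/pixel) over an ROI."""
    density = _density_array(cell_density_map)
    ys, xs = pixels.indices()
    count = float(density[ys, xs].sum())
    return count, count / pixels.n_pixels


def cell_corrected_ratio(
    grid: ChannelGrid,
    pixels: RoiMask,
    analyte: str,
    reference: str,
    cell_density_map: ChannelGrid | np.ndarray,
    calibration_density: float,
) -> float:
    """Summed ratio corrected for the ROI's intact-cell density.

    ``corrected = summed_ratio × calibration_density / roi_mean_density``
    with ``roi_mean_density = cell_count / n_pixels``.  The lipid reference
    scales with intact-cell density, so ratios from regions whose density
    differs from the homogenate calibrants are rescaled to the calibration
    condition; equal densities leave the ratio unchanged.
    """
    if not calibration_density > 0:
        raise RoiError(f"calibration_density must be > 0, got {calibration_density}")
    _, mean_density = roi_cell_stats(pixels, cell_density_map)
    if mean_density == 0:
        raise RoiError(f"ROI {pixels.name!r}: zero mean cell density, cannot correct")
    return summed_ratio(grid, pixels, analyte, reference) * calibration_density / mean_density


def _summary_flag(
    replicate_flags: Sequence[str], mean_conc: float, curve: CalibrationCurve
) -> str:
    """Classify the ROI mean; any replicate beyond the ULOQ taints the ROI."""
    if any(f == FLAG_ABOVE_ULOQ for f in replicate_flags):
        return FLAG_ABOVE_ULOQ
    if mean_conc < curve.lod:
        return FLAG_BELOW_LOD
    if mean_conc < curve.lloq:
        return FLAG_BELOW_LLOQ
    if mean_conc > curve.uloq:
        return FLAG_ABOVE_ULOQ
    return FLAG_OK


def quantify_rois(
    grid: ChannelGrid,
    rois: Mapping[str, Sequence[RoiMask]],
    curve: CalibrationCurve,
    analyte: str,
    reference: str,
    cell_density_map: ChannelGrid | np.ndarray,
    calibration_density: float,
    transform: RegistrationTransform | None = None,
) -> list[RoiQuantResult]:
    """Quantify each ROI (with replicate masks) through the calibration curve.

    Per replicate: register (optional), cell-correct the summed ratio, and
    back-calculate.  Per ROI: mean ± sample SD over replicates, with flags
    propagated (any replicate above the ULOQ marks the ROI ``above_uloq``).
    An analyte channel that is zero everywhere yields ``nd`` rows with no
    concentrations, mirroring a transition that was not acquired.
    """
    nd = analyte not in grid.intensities or not np.any(grid[analyte] > 0)
    results: list[RoiQuantResult] = []
    for roi_name, masks in rois.items():
        if not masks:
            raise RoiError(f"ROI {roi_name!r}: no replicate masks")
        if transform is not None:
            masks = [register_and_extract(grid, m, transform) for m in masks]
        total_px = sum(m.n_pixels for m in masks)
        total_cells = sum(roi_cell_stats(m, cell_density_map)[0] for m in masks)
        if nd:
            results.append(
                RoiQuantResult(
                    roi_name=roi_name,
                    n_pixels=total_px,
                    cell_count=total_cells,
                    raw_ratio=None,
                    corrected_ratio=None,
                    conc=None,
                    flag=FLAG_ND,
                    conc_sd=None,
                    n_replicates=len(masks),
                    replicate_concs=(),
                )
            )
            continue
        raw, corrected, concs, flags = [], [], [], []
        for m in masks:
            raw.append(summed_ratio(grid, m, analyte, reference))
            corr = cell_corrected_ratio(
                grid, m, analyte, reference, cell_density_map, calibration_density
            )
            corrected.append(corr)
            conc, flag = back_calculate(curve, corr)
            concs.append(conc)
            flags.append(flag)
        results.append(
            RoiQuantResult(
                roi_name=roi_name,
                n_pixels=total_px,
                cell_count=total_cells,
                raw_ratio=float(np.mean(raw)),
                corrected_ratio=float(np.mean(corrected)),
                conc=float(np.mean(concs)),
                flag=_summary_flag(flags, float(np.mean(concs)), curve),
                conc_sd=float(np.std(concs, ddof=1)) if len(concs) >= 2 else None,
                n_replicates=len(masks),
                replicate_concs=tuple(concs),
            )
        )
    return results


def fold_differences(table: pd.DataFrame | Mapping[str, float]) -> pd.DataFrame:
    """Pairwise fold differences between labelled concentrations.

    ``table`` is either a mapping label → concentration or a DataFrame with
    columns ``label``, ``conc`` and optionally ``flag``.  Each pair yields
    one row with the larger/smaller labels and ``fold = larger / smaller``
    (full precision; display rounding is the reporter's job).  Pairs with a
    non-``ok`` flag or a zero denominator are kept with a note and no fold.
    """
    if isinstance(table, Mapping):
        df = pd.DataFrame({"label": list(table), "conc": list(table.values())})
    else:
        df = table.copy()
    if "flag" not in df.columns:
        df["flag"] = FLAG_OK
    rows = []
    for (_, a), (_, b) in itertools.combinations(df.iterrows(), 2):
        bad = [r["label"] for r in (a, b) if r["flag"] not in (FLAG_OK, None)]
        if bad:
            rows.append(
                {
                    "label_high": None,
                    "label_low": None,
                    "fold": np.nan,
                    "note": "skipped (flagged: " + ", ".join(f"{r}" for r in bad) + ")",
                    "pair": f"{a['label']}/{b['label']}",
                }
            )
            continue
        hi, lo = (a, b) if a["conc"] >= b["conc"] else (b, a)
        if lo["conc"] == 0:
            rows.append(
                {
                    "label_high": hi["label"],
                    "label_low": lo["label"],
                    "fold": np.nan,
                    "note": "skipped (zero denominator)",
                    "pair": f"{a['label']}/{b['label']}",
                }
            )
            continue
        rows.append(
            {
                "label_high": hi["label"],
                "label_low": lo["label"],
                "fold": float(hi["conc"]) / float(lo["conc"]),
                "note": "",
                "pair": f"{a['label']}/{b['label']}",
            }
        )
    return pd.DataFrame(rows, columns=["label_high", "label_low", "fold", "note", "pair"])


def format_fold(fold: float) -> str:
    """1-decimal display rounding used in reports."""
    return f"{fold:.1f}"


def lcms_concordance(
    msi_concs: Mapping[str, float], lcms: Sequence[LcmsRange]
) -> tuple[dict[str, float], float]:
    """Fold difference of MSI parenchyma concentrations vs LC-MS ranges.

    A value inside its sample's range scores fold 1; otherwise the fold is
    the ratio to the nearest range bound, so folds are always ≥ 1 (the
    conservative reading of a range-valued reference).  Returns the
    per-sample folds and their maximum.  Sample-id sets must match exactly.
    """
    lcms_by_id = {r.sample_id: r for r in lcms}
    if len(lcms_by_id) != len(lcms):
        raise ConcordanceError("duplicate sample ids in LC-MS ranges")
    unmatched = sorted(set(msi_concs) ^ set(lcms_by_id))
    if unmatched:
        raise ConcordanceError(f"unmatched sample ids: {unmatched}")
    folds: dict[str, float] = {}
    for sid, value in msi_concs.items():
        rng = lcms_by_id[sid]
        if rng.low <= value <= rng.high:
            folds[sid] = 1.0
        elif value < rng.low:
            if value <= 0:
                raise ConcordanceError(f"sample {sid!r}: non-positive MSI concentration {value}")
            folds[sid] = rng.low / value
        else:
            folds[sid] = value / rng.high
    return folds, max(folds.values())


def diffusion_check(
    grid: ChannelGrid,
    layout: ArrayLayout,
    corridor_margin_px: int,
    channels: Sequence[str] | None = None,
    background_margin_px: int | None = None,
) -> dict[str, float]:
    """Fraction of well signal leaking into the inter-well gelatin corridor.

    For each channel: ``max(0, (mean corridor − mean background) / D)``
    where the corridor is every non-well pixel inside the well bounding box
    at ≥ ``corridor_margin_px`` from any well, the far background is every
    pixel outside the bounding box at ≥ ``background_margin_px`` (default
    twice the corridor margin) from any well, and ``D`` averages, over
    corridor pixels, the within-well mean intensity of each pixel's nearest
    well.  Zero diffusion yields ≈ 0; the fraction grows with the diffusion
    length because corridor pixels sit closer to the wells than the far
    background does.
    """
    if len(layout.wells) < 2:
        raise GeometryError("diffusion check needs a layout with >= 2 wells")
    if channels is None:
        channels = [c.name for c in grid.channels if c.kind == "analyte"]
    if background_margin_px is None:
        background_margin_px = 2 * corridor_margin_px
    h, w = grid.height, grid.width
    well_mask = np.zeros((h, w), dtype=bool)
    well_index = np.full((h, w), -1)
    for i, well in enumerate(layout.wells):
        sl = (slice(well.y0, well.y0 + well.height), slice(well.x0, well.x0 + well.width))
        well_mask[sl] = True
        well_index[sl] = i
    dist, (iy, ix) = distance_transform_edt(~well_mask, return_indices=True)
    nearest = well_index[iy, ix]

    x0, y0, x1, y1 = layout.bounding_box()
    inside_bbox = np.zeros((h, w), dtype=bool)
    inside_bbox[y0:y1, x0:x1] = True
    corridor = inside_bbox & ~well_mask & (dist >= corridor_margin_px)
    if not corridor.any():
        raise GeometryError(f"no corridor pixels at margin {corridor_margin_px}")
    background = ~inside_bbox & (dist >= background_margin_px)
    if not background.any():
        raise GeometryError(
            f"no far-background pixels at distance >= {background_margin_px} from the wells"
        )

    fractions: dict[str, float] = {}
    for ch in channels:
        img = grid[ch]
        well_means = np.array(
            [img[wl.y0 : wl.y0 + wl.height, wl.x0 : wl.x0 + wl.width].mean() for wl in layout.wells]
        )
        denom = float(well_means[nearest[corridor]].mean())
        if denom == 0:
            fractions[ch] = 0.0
            continue
        excess = float(img[corridor].mean()) - float(img[background].mean())
        fractions[ch] = max(0.0, excess / denom)
    return fractions
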
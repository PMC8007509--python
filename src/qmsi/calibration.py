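"""Calibration curves, detection limits, QC evaluation, and back-calculation.

The quantification chain works entirely on analyte-to-lipid intensity
ratios: spectra from an ROI are summed first and the ratio of sums is taken
(never the mean of per-pixel ratios), which suppresses pixel-to-pixel
variability and tissue ion suppression shared by both channels.  Ordinary
(unweighted) least squares of the per-level mean ratio against nominal
concentration gives slope and intercept; detection limits follow the blank
variability convention

    LOD  = 3 · SD_blank / slope
    LLOQ = 5 · SD_blank / slope

with ``SD_blank`` the sample standard deviation (n − 1) of the blank
replicate-ROI ratios.  Calibration levels whose nominal concentration falls
below the current LOD are excluded and the curve refit until the excluded
set is stable.  QC acceptance follows bioanalytical characterization
criteria: precision ≤ 15 % RSD (≤ 20 % at the LLOQ) and accuracy within
−20 % to +10 % of nominal (80–110 %).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationError, UndefinedRatioError
from .grid import ChannelGrid, RoiMask
from .layout import ROLE_BLANK, ROLE_CALIBRATION, ROLE_QC, ArrayLayout

FLAG_OK = "ok"
FLAG_BELOW_LOD = "below_lod"
FLAG_BELOW_LLOQ = "below_lloq"
FLAG_ABOVE_ULOQ = "above_uloq"
FLAG_ND = "nd"


@dataclass(frozen=True)
class RatioObservation:
    """One summed analyte/lipid ratio from one ROI of one well."""

    well_id: str
    role: str
    nominal_conc: float
    ratio: float
    replicate_id: int
    n_pixels: int

    def __post_init__(self) -> None:
        if self.ratio < 0 or not math.isfinite(self.ratio):
            raise CalibrationError(f"{self.well_id}: ratio must be finite and >= 0, got {self.ratio}")
        if self.n_pixels < 1:
            raise CalibrationError(f"{self.well_id}: n_pixels must be >= 1")
        if self.role == ROLE_BLANK and self.nominal_conc != 0:
            raise CalibrationError(f"blank observation {self.well_id} has nonzero nominal")


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted analyte calibration line with detection limits."""

    slope: float
    intercept: float
    r_squared: float
    sd_blank: float
    lod: float
    lloq: float
    uloq: float
    included_levels: tuple[float, ...]
    excluded_levels: tuple[float, ...]
    n_refits: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "sd_blank": self.sd_blank,
            "lod_ug_g": self.lod,
            "lloq_ug_g": self.lloq,
            "uloq_ug_g": self.uloq,
            "included_levels": list(self.included_levels),
            "excluded_levels": list(self.excluded_levels),
            "n_refits": self.n_refits,
        }


@dataclass(frozen=True)
class QcCriteria:
    """Method characterization thresholds for QC samples."""

    precision_rsd_max: float = 15.0
    precision_rsd_max_at_lloq: float = 20.0
    accuracy_min_pct: float = 80.0
    accuracy_max_pct: float = 110.0


@dataclass(frozen=True)
class QcResult:
    nominal_conc: float
    n: int
    mean_measured: float
    precision_rsd: float
    accuracy_pct: float
    below_lloq: bool
    passes_precision: bool
    passes_accuracy: bool

    def to_dict(self) -> dict:
        return {
            "nominal_conc_ug_g": self.nominal_conc,
            "n": self.n,
            "mean_measured_ug_g": self.mean_measured,
            "precision_rsd_pct": self.precision_rsd,
            "accuracy_pct": self.accuracy_pct,
            "below_lloq": self.below_lloq,
            "passes_precision": self.passes_precision,
            "passes_accuracy": self.passes_accuracy,
        }


class BackCalcResult(NamedTuple):
    conc: float
    flag: str


def summed_ratio(grid: ChannelGrid, pixels: RoiMask, analyte: str, reference: str) -> float:
    """Ratio of summed intensities over an ROI: Σ analyte / Σ reference."""
    pixels.check_bounds(grid)
    ys, xs = pixels.indices()
    num = float(grid[analyte][ys, xs].sum())
    den = float(grid[reference][ys, xs].sum())
    if den == 0:
        raise UndefinedRatioError(
            f"ROI {pixels.name!r}: reference channel {reference!r} sums to zero"
        )
    return num / den


def fit_line(observations: Sequence[RatioObservation]) -> tuple[float, float, float]:
    """OLS of per-level mean ratio vs nominal concentration.

    Returns ``(slope, intercept, r_squared)``.  Replicate ratios at the same
    nominal level are averaged before fitting, so every level carries equal
    weight regardless of replicate count.
    """
    levels: dict[float, list[float]] = {}
    for obs in observations:
        levels.setdefault(float(obs.nominal_conc), []).append(obs.ratio)
    if len(levels) < 3:
        raise CalibrationError(
            f"calibration needs >= 3 distinct concentration levels, got {len(levels)}"
        )
    x = np.array(sorted(levels))
    y = np.array([float(np.mean(levels[c])) for c in x])
    if np.ptp(x) == 0:
        raise CalibrationError("degenerate design: zero concentration variance")
    if np.ptp(y) == 0:  # flat response: slope 0, no explained variance
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def compute_lod(sd_blank: float, slope: float) -> float:
    """Limit of detection in µg/g: 3 · SD_blank / slope."""
    if slope <= 0:
        raise CalibrationError(f"invalid curve: slope must be > 0, got {slope}")
    if sd_blank < 0:
        raise CalibrationError(f"sd_blank must be >= 0, got {sd_blank}")
    return 3.0 * sd_blank / slope


def compute_lloq(sd_blank: float, slope: float) -> float:
    """Lower limit of quantification in µg/g: 5 · SD_blank / slope."""
    if slope <= 0:
        raise CalibrationError(f"invalid curve: slope must be > 0, got {slope}")
    if sd_blank < 0:
        raise CalibrationError(f"sd_blank must be >= 0, got {sd_blank}")
    return 5.0 * sd_blank / slope


def _blank_ratios(blanks: Iterable) -> list[float]:
    out = []
    for b in blanks:
        out.append(float(b.ratio) if isinstance(b, RatioObservation) else float(b))
    return out


def build_calibration(
    observations: Sequence[RatioObservation],
    blanks: Sequence,
    max_refits: int = 20,
) -> CalibrationCurve:
    """Fit a calibration curve with iterative below-LOD exclusion.

    ``blanks`` is a sequence of blank replicate ratios (floats or blank
    :class:`RatioObservation`s; at least 2).  The procedure fits all levels,
    computes the LOD, drops levels whose nominal concentration is below it,
    refits, and repeats until the excluded set is stable.  Exclusion leaving
    fewer than 3 levels is a calibration failure.
    """
    cal_obs = [o for o in observations if o.role == ROLE_CALIBRATION]
    blank_ratios = _blank_ratios(blanks)
    if len(blank_ratios) < 2:
        raise CalibrationError(f"need >= 2 blank replicate ratios, got {len(blank_ratios)}")
    sd_blank = float(np.std(blank_ratios, ddof=1))
    all_levels = sorted({float(o.nominal_conc) for o in cal_obs})

    included = set(all_levels)
    n_refits = 0
    lod = math.nan
    for _ in range(max_refits):
        subset = [o for o in cal_obs if float(o.nominal_conc) in included]
        slope, intercept, r2 = fit_line(subset)
        n_refits += 1
        lod = compute_lod(sd_blank, slope)
        new_included = {c for c in all_levels if c >= lod}
        if len(new_included) < 3:
            raise CalibrationError(
                f"exclusion at LOD {lod:.4g} ug/g leaves "
                f"{len(new_included)} levels (< 3): calibration failed"
            )
        if new_included == included:
            break
        included = new_included
    lloq = compute_lloq(sd_blank, slope)
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        sd_blank=sd_blank,
        lod=lod,
        lloq=lloq,
        uloq=max(included),
        included_levels=tuple(sorted(included)),
        excluded_levels=tuple(sorted(set(all_levels) - included)),
        n_refits=n_refits,
    )


def back_calculate(curve: CalibrationCurve, ratio: float) -> BackCalcResult:
    """Invert the calibration line and flag the result.

    ``conc = (ratio − intercept) / slope``; flagged ``below_lod`` when
    conc < LOD, ``below_lloq`` when LOD ≤ conc < LLOQ, ``above_uloq`` when
    conc > ULOQ (extrapolation beyond the highest included level).
    """
    if curve.slope <= 0:
        raise CalibrationError("invalid curve: slope must be > 0")
    conc = (ratio - curve.intercept) / curve.slope
    if conc < curve.lod:
        flag = FLAG_BELOW_LOD
    elif conc < curve.lloq:
        flag = FLAG_BELOW_LLOQ
    elif conc > curve.uloq:
        flag = FLAG_ABOVE_ULOQ
    else:
        flag = FLAG_OK
    return BackCalcResult(float(conc), flag)


def evaluate_qc(
    replicate_concs: Sequence[float],
    nominal: float,
    lloq: float,
    criteria: QcCriteria = QcCriteria(),
) -> QcResult:
    """Precision (%RSD) and accuracy (% of nominal) of QC replicates."""
    concs = np.asarray(replicate_concs, dtype=float)
    if concs.size < 2:
        raise CalibrationError(f"QC evaluation needs n >= 2 replicates, got {concs.size}")
    mean = float(concs.mean())
    if mean == 0:
        raise CalibrationError("QC replicate mean is zero: RSD undefined")
    rsd = 100.0 * float(np.std(concs, ddof=1)) / mean
    accuracy = 100.0 * mean / nominal
    rsd_limit = (
        criteria.precision_rsd_max_at_lloq
        if nominal <= lloq
        else criteria.precision_rsd_max
    )
    return QcResult(
        nominal_conc=float(nominal),
        n=int(concs.size),
        mean_measured=mean,
        precision_rsd=rsd,
        accuracy_pct=accuracy,
        below_lloq=mean < lloq,
        passes_precision=rsd <= rsd_limit,
        passes_accuracy=criteria.accuracy_min_pct <= accuracy <= criteria.accuracy_max_pct,
    )


def observe_array(
    grid: ChannelGrid,
    layout: ArrayLayout,
    analyte: str,
    reference: str,
    n_replicates: int = 3,
) -> list[RatioObservation]:
    """Extract replicate summed ratios from every well of a mimetic array.

    Calibration and QC wells are split into ``n_replicates`` vertical strip
    sub-ROIs (replicate ratios for regression and QC statistics); blank
    wells contribute one whole-well ROI each, so the blank SD is taken over
    the blank replicate wells.
    """
    observations: list[RatioObservation] = []
    for well in layout.wells:
        if well.role == ROLE_BLANK:
            masks = [well.mask()]
            rep_ids = [well.replicate_id]
        else:
            masks = well.strip_masks(n_replicates)
            rep_ids = list(range(1, n_replicates + 1))
        nominal = well.nominal_conc.get(analyte, 0.0)
        for rep_id, mask in zip(rep_ids, masks):
            observations.append(
                RatioObservation(
                    well_id=well.well_id,
                    role=well.role,
                    nominal_conc=float(nominal),
                    ratio=summed_ratio(grid, mask, analyte, reference),
                    replicate_id=rep_id,
                    n_pixels=mask.n_pixels,
                )
            )
    return observations


def qc_replicate_ratios(observations: Sequence[RatioObservation]) -> dict[float, list[float]]:
    """Group QC observations by nominal level → replicate ratios."""
    out: dict[float, list[float]] = {}
    for o in observations:
        if o.role == ROLE_QC:
            out.setdefault(float(o.nominal_conc), []).append(o.ratio)
    return out
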
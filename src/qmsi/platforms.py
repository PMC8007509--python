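"""Multi-instrument / multi-mode comparison tables.

Each acquisition mode (e.g. full MS scan, ion-mobility HDMS/HDMSE, or MRM on
a triple quadrupole) contributes calibration observations, blank ratios, and
QC replicate ratios per compound.  :func:`summarize_mode` runs the standard
calibration + QC evaluation per compound and reproduces the reporting
conventions of a characterization table: QC levels whose nominal
concentration falls below that mode's LOD are rendered ``<LOD`` with their
precision/accuracy suppressed.  :func:`rank_modes` orders modes by how many
characterization criteria they pass, then by sensitivity and linearity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .calibration import (
    CalibrationCurve,
    QcCriteria,
    QcResult,
    back_calculate,
    build_calibration,
    evaluate_qc,
    RatioObservation,
)
from .errors import CalibrationError

logger = logging.getLogger(__name__)


@dataclass
class CompoundData:
    """Calibration + QC raw material for one compound in one mode."""

    calibration: list[RatioObservation]
    blank_ratios: list[float]
    qc_ratios: dict[float, list[float]]  # nominal µg/g -> replicate ratios


@dataclass
class ModeDataset:
    """One instrument/mode acquisition of the shared mimetic array layout."""

    instrument: str
    mode: str
    compounds: dict[str, CompoundData]

    @property
    def key(self) -> str:
        return f"{self.instrument}/{self.mode}"


@dataclass
class PlatformSummaryRow:
    """Per (instrument, mode, compound) characterization metrics."""

    instrument: str
    mode: str
    compound: str
    lod: float | None = None
    r_squared: float | None = None
    curve: CalibrationCurve | None = None
    qc: dict[float, QcResult | None] = field(default_factory=dict)  # None => below LOD
    qc_low_below_lod: bool = False
    criteria_pass: bool = False
    error: str | None = None

    @property
    def n_criteria_passed(self) -> int:
        """Precision then accuracy passes over the evaluable QC levels (0–4)."""
        n = 0
        for res in self.qc.values():
            if res is not None:
                n += int(res.passes_precision) + int(res.passes_accuracy)
        return n


def summarize_mode(
    dataset: ModeDataset, criteria: QcCriteria = QcCriteria()
) -> list[PlatformSummaryRow]:
    """Calibrate and QC-evaluate every compound of one mode.

    A calibration failure produces a failed row (with the error recorded)
    rather than aborting the whole table.
    """
    rows: list[PlatformSummaryRow] = []
    for compound in sorted(dataset.compounds):
        data = dataset.compounds[compound]
        row = PlatformSummaryRow(dataset.instrument, dataset.mode, compound)
        try:
            curve = build_calibration(data.calibration, data.blank_ratios)
        except CalibrationError as exc:
            row.error = str(exc)
            rows.append(row)
            continue
        row.curve = curve
        row.lod = curve.lod
        row.r_squared = curve.r_squared
        low_qc = min(data.qc_ratios) if data.qc_ratios else None
        all_pass = bool(data.qc_ratios)
        for nominal in sorted(data.qc_ratios):
            if nominal < curve.lod:
                row.qc[nominal] = None  # rendered "<LOD"
                if nominal == low_qc:
                    row.qc_low_below_lod = True
                all_pass = False
                continue
            concs = [back_calculate(curve, r).conc for r in data.qc_ratios[nominal]]
            res = evaluate_qc(concs, nominal, curve.lloq, criteria)
            row.qc[nominal] = res
            all_pass = all_pass and res.passes_precision and res.passes_accuracy
        row.criteria_pass = all_pass
        rows.append(row)
    return rows


def summary_table(rows: list[PlatformSummaryRow]) -> pd.DataFrame:
    """Characterization-table rendering with the ``<LOD`` convention."""
    records = []
    for r in rows:
        rec: dict = {
            "instrument": r.instrument,
            "mode": r.mode,
            "compound": r.compound,
        }
        if r.error is not None:
            rec.update({"lod_ug_g": None, "r_squared": None, "status": f"failed: {r.error}"})
        else:
            rec.update(
                {
                    "lod_ug_g": round(r.lod, 4),
                    "r_squared": round(r.r_squared, 4),
                    "status": "pass" if r.criteria_pass else "fail",
                }
            )
            for nominal in sorted(r.qc):
                res = r.qc[nominal]
                tag = f"{nominal:g}"
                if res is None:
                    rec[f"precision_rsd_{tag}"] = "<LOD"
                    rec[f"accuracy_pct_{tag}"] = "<LOD"
                else:
                    rec[f"precision_rsd_{tag}"] = round(res.precision_rsd, 2)
                    rec[f"accuracy_pct_{tag}"] = round(res.accuracy_pct, 1)
        records.append(rec)
    return pd.DataFrame(records)


@dataclass
class RankResult:
    """Per-compound mode ordering plus an overall order across compounds."""

    per_compound: dict[str, list[str]]  # compound -> mode keys, best first
    best_per_compound: dict[str, str]
    overall: list[str]


def _sort_stable(keys: list[str], scores: dict[str, tuple], label: str) -> list[str]:
    order = sorted(range(len(keys)), key=lambda i: scores[keys[i]])
    ranked = [keys[i] for i in order]
    for a, b in zip(ranked, ranked[1:]):
        if scores[a] == scores[b]:
            logger.info("ranking tie (%s): %s vs %s resolved by input order", label, a, b)
    return ranked


def rank_modes(rows: list[PlatformSummaryRow]) -> RankResult:
    """Order modes: criteria passed (desc), then LOD (asc), then R² (desc).

    Failed calibrations sort last.  Ties keep input order (logged).
    Returns the per-compound ordering (best mode first) and an overall
    ordering aggregated over compounds (total criteria passed, mean LOD,
    mean R²).
    """
    mode_keys: list[str] = []
    for r in rows:
        key = f"{r.instrument}/{r.mode}"
        if key not in mode_keys:
            mode_keys.append(key)
    if len(mode_keys) < 2:
        raise CalibrationError("ranking needs >= 2 modes")

    by_compound: dict[str, dict[str, PlatformSummaryRow]] = {}
    for r in rows:
        by_compound.setdefault(r.compound, {})[f"{r.instrument}/{r.mode}"] = r

    inf = float("inf")
    per_compound: dict[str, list[str]] = {}
    for compound, per_mode in by_compound.items():
        scores = {}
        for key in mode_keys:
            r = per_mode.get(key)
            if r is None or r.error is not None:
                scores[key] = (0, inf, inf)
            else:
                scores[key] = (-r.n_criteria_passed, r.lod, -r.r_squared)
        per_compound[compound] = _sort_stable(mode_keys, scores, compound)

    totals = {}
    for key in mode_keys:
        passed, lods, r2s = 0, [], []
        for per_mode in by_compound.values():
            r = per_mode.get(key)
            if r is not None and r.error is None:
                passed += r.n_criteria_passed
                lods.append(r.lod)
                r2s.append(r.r_squared)
        mean = lambda v: sum(v) / len(v) if v else inf
        totals[key] = (-passed, mean(lods), -mean(r2s) if r2s else inf)
    overall = _sort_stable(mode_keys, totals, "overall")

    return RankResult(
        per_compound=per_compound,
        best_per_compound={c: order[0] for c, order in per_compound.items()},
        overall=overall,
    )
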
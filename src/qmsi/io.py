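"""Readers and writers for the pipeline's plain-text data formats.

Native formats (all diffable text):

* **Channel grid** — a TSV with columns ``x  y  channel  intensity`` plus a
  JSON sidecar (same path with ``.json`` instead of ``.tsv``) declaring the
  raster dimensions, pixel size, and channel definitions.  Pixels absent
  from the TSV read as intensity 0 (with a logged count); channels appearing
  in the TSV must be declared in the sidecar.
* **ROI mask** — a TSV of 0-based ``x  y`` pixel coordinates (header row).
* **Array layout** — YAML or JSON listing the wells.

imzML is import-only, for bridging to real acquisitions: each channel is the
per-pixel sum of signal inside an m/z window.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import GridFormatError, LayoutError, RoiError
from .grid import ChannelDef, ChannelGrid, RoiMask
from .layout import ArrayLayout, Well

logger = logging.getLogger(__name__)


def _sidecar_path(tsv_path: Path) -> Path:
    return tsv_path.with_suffix(".json")


def write_grid(grid: ChannelGrid, path: str | Path) -> Path:
    """Write a grid as TSV + JSON sidecar; returns the TSV path.

    Zero-intensity pixels are omitted from the TSV (they read back as 0).
    """
    path = Path(path)
    rows = []
    for name in grid.channel_names:
        arr = grid[name]
        ys, xs = np.nonzero(arr)
        rows.append(
            pd.DataFrame(
                {"x": xs, "y": ys, "channel": name, "intensity": arr[ys, xs]}
            )
        )
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["x", "y", "channel", "intensity"]
    )
    table.to_csv(path, sep="\t", index=False)
    sidecar = {
        "width": grid.width,
        "height": grid.height,
        "pixel_size_um": grid.pixel_size_um,
        "channels": [
            {
                "name": c.name,
                "kind": c.kind,
                "mrm_precursor_mz": c.mrm_precursor_mz,
                "mrm_fragment_mz": c.mrm_fragment_mz,
            }
            for c in grid.channels
        ],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_grid(path: str | Path) -> ChannelGrid:
    """Read a TSV + JSON-sidecar channel grid."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise GridFormatError(f"missing JSON sidecar {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    channels = [
        ChannelDef(
            name=c["name"],
            kind=c.get("kind", "analyte"),
            mrm_precursor_mz=c.get("mrm_precursor_mz"),
            mrm_fragment_mz=c.get("mrm_fragment_mz"),
        )
        for c in meta["channels"]
    ]
    width, height = int(meta["width"]), int(meta["height"])
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    expected_cols = {"x", "y", "channel", "intensity"}
    if not expected_cols.issubset(table.columns):
        raise GridFormatError(f"grid TSV must have columns {sorted(expected_cols)}")
    declared = {c.name for c in channels}
    undeclared = set(table["channel"].unique()) - declared
    if undeclared:
        raise GridFormatError(f"channels in TSV absent from sidecar: {sorted(undeclared)}")
    if table.duplicated(subset=["x", "y", "channel"]).any():
        dupes = table[table.duplicated(subset=["x", "y", "channel"], keep=False)]
        raise GridFormatError(
            f"duplicate (x, y, channel) rows in grid TSV, e.g. "
            f"{dupes.iloc[0][['x', 'y', 'channel']].tolist()}"
        )
    if table["intensity"].isna().any() or not np.isfinite(table["intensity"]).all():
        raise GridFormatError("grid TSV contains NaN or non-finite intensities")
    if (table["intensity"] < 0).any():
        raise GridFormatError("grid TSV contains negative intensities")
    oob = (table["x"] < 0) | (table["x"] >= width) | (table["y"] < 0) | (table["y"] >= height)
    if oob.any():
        bad = table[oob].iloc[0]
        raise GridFormatError(
            f"pixel ({bad['x']}, {bad['y']}) outside declared {width}x{height} grid"
        )

    intensities = {name: np.zeros((height, width)) for name in declared}
    n_missing = 0
    for name in declared:
        sub = table[table["channel"] == name]
        arr = intensities[name]
        arr[sub["y"].to_numpy(int), sub["x"].to_numpy(int)] = sub["intensity"].to_numpy(float)
        n_missing += width * height - len(sub)
    if n_missing:
        logger.warning("%s: %d (pixel, channel) entries absent, read as 0", path.name, n_missing)
    return ChannelGrid(
        pixel_size_um=float(meta["pixel_size_um"]), channels=channels, intensities=intensities
    )


def write_roi_mask(mask: RoiMask, path: str | Path) -> Path:
    path = Path(path)
    ys, xs = mask.indices()
    pd.DataFrame({"x": xs, "y": ys}).to_csv(path, sep="\t", index=False)
    return path


def read_roi_mask(path: str | Path, name: str | None = None) -> RoiMask:
    """Read an ROI mask TSV; duplicate rows are de-duplicated with a log note."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    if not {"x", "y"}.issubset(table.columns):
        raise RoiError(f"{path}: ROI TSV must have columns x, y")
    if table.empty:
        raise RoiError(f"{path}: ROI mask is empty")
    pixels = frozenset(zip(table["x"].astype(int), table["y"].astype(int)))
    if len(pixels) < len(table):
        logger.info("%s: %d duplicate rows de-duplicated", path.name, len(table) - len(pixels))
    return RoiMask(name or path.stem, pixels)


def write_layout(layout: ArrayLayout, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "grid_width": layout.grid_width,
        "grid_height": layout.grid_height,
        "wells": [
            {
                "well_id": w.well_id,
                "role": w.role,
                "nominal_conc": w.nominal_conc,
                "replicate_id": w.replicate_id,
                "x0": w.x0,
                "y0": w.y0,
                "width": w.width,
                "height": w.height,
            }
            for w in layout.wells
        ],
    }
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=1))
    return path


def read_layout(path: str | Path) -> ArrayLayout:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    try:
        wells = [
            Well(
                well_id=w["well_id"],
                role=w["role"],
                nominal_conc={k: float(v) for k, v in w["nominal_conc"].items()},
                replicate_id=int(w.get("replicate_id", 1)),
                x0=int(w["x0"]),
                y0=int(w["y0"]),
                width=int(w["width"]),
                height=int(w["height"]),
            )
            for w in doc["wells"]
        ]
        return ArrayLayout(
            grid_width=int(doc["grid_width"]), grid_height=int(doc["grid_height"]), wells=wells
        )
    except (KeyError, TypeError) as exc:
        raise LayoutError(f"{path}: malformed layout document ({exc})") from exc


def import_imzml(
    path: str | Path,
    channel_windows: list[tuple[str, float, float]],
    pixel_size_um: float | None = None,
) -> ChannelGrid:
    """Import an imzML file as a channel grid.

    ``channel_windows`` is a list of ``(name, mz_center, tolerance)``; each
    channel's per-pixel intensity is the sum of all signal within
    ``mz_center ± tolerance``.  Pixels absent from the file stay 0.  A
    window that no spectrum overlaps anywhere yields an all-zero channel
    with a logged warning.
    """
    from pyimzml.ImzMLParser import ImzMLParser  # binary .ibd dependency: import-only

    parser = ImzMLParser(str(path))
    width = int(parser.imzmldict["max count of pixels x"])
    height = int(parser.imzmldict["max count of pixels y"])
    if pixel_size_um is None:
        pixel_size_um = float(parser.imzmldict.get("pixel size x", 1.0) or 1.0)
    intensities = {name: np.zeros((height, width)) for name, _, _ in channel_windows}
    hits = {name: 0 for name, _, _ in channel_windows}
    for idx, (x, y, _z) in enumerate(parser.coordinates):
        mzs, ints = parser.getspectrum(idx)
        mzs = np.asarray(mzs)
        ints = np.asarray(ints)
        for name, center, tol in channel_windows:
            sel = np.abs(mzs - center) <= tol
            if sel.any():
                intensities[name][y - 1, x - 1] += float(ints[sel].sum())
                hits[name] += 1
    for name, n in hits.items():
        if n == 0:
            logger.warning("imzML %s: no spectrum overlaps window %r; channel all zero", path, name)
    channels = [ChannelDef(name, "analyte", center, None) for name, center, _ in channel_windows]
    return ChannelGrid(pixel_size_um=pixel_size_um, channels=channels, intensities=intensities)
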
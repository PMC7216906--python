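"""File formats: compositions, measurements, calibration tables, images.

* Compositions: CSV with header ``name,rho_g_cm3,<element symbols...>,
  w_res,zbar_res`` (weights in percent by default) or an equivalent JSON
  list of records.
* Measurements: CSV ``material,hu,hu_sd`` with material names resolved
  against the bundled datasets or a user-supplied composition file.
* Calibration tables: CSV ``hu,value`` preceded by a ``# kind: MD|RED``
  comment line; the same format reads RTPS-registered tables.
* Images: plain CSV grids of HU values (one row per image row) and
  single-frame DICOM CT with rescale slope/intercept applied.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .datasets import get_material
from .materials import ELEMENTS, MaterialComposition, normalize_weights
from .model import AttenuationParams, CTMeasurement, FitResult
from .tissues import CalibrationPoint, CalibrationTable

__all__ = [
    "read_compositions",
    "read_measurements",
    "write_table",
    "read_table",
    "write_image_csv",
    "read_image_csv",
    "read_dicom_image",
    "fit_report_dict",
    "write_fit_report",
    "read_fit_report",
]

PathLike = Union[str, Path]

_META_COLS = {"name", "rho_g_cm3", "w_res", "zbar_res"}


def _row_to_composition(row: dict, percent: bool) -> MaterialComposition:
    scale = 0.01 if percent else 1.0
    weights = {}
    for key, val in row.items():
        if key in _META_COLS or val is None:
            continue
        if isinstance(val, float) and np.isnan(val):
            continue
        if key not in ELEMENTS:
            raise KeyError(f"unknown element column {key!r}")
        weights[key] = float(val) * scale
    residual = None
    w_res = row.get("w_res")
    if w_res is not None and not (isinstance(w_res, float) and np.isnan(w_res)) \
            and float(w_res) > 0:
        residual = (float(w_res) * scale, float(row["zbar_res"]))
    return normalize_weights(
        MaterialComposition(str(row["name"]), float(row["rho_g_cm3"]),
                            weights, residual)
    )


def read_compositions(path: PathLike, percent: bool = True) -> dict[str, MaterialComposition]:
    """Read a composition CSV or JSON file into a name-keyed dict."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict(orient="records")
    out = {}
    for row in records:
        m = _row_to_composition(dict(row), percent)
        out[m.name] = m
    return out


def read_measurements(
    path: PathLike,
    compositions: Optional[dict[str, MaterialComposition]] = None,
) -> list[CTMeasurement]:
    """Read a ``material,hu,hu_sd`` CSV, resolving material names against
    ``compositions`` first and the bundled datasets second."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no measurements found")
    out = []
    for row in df.itertuples(index=False):
        name = str(row.material)
        if compositions and name in compositions:
            material = compositions[name]
        else:
            material = get_material(name)
        sd = getattr(row, "hu_sd", None)
        if sd is not None and np.isnan(sd):
            sd = None
        out.append(CTMeasurement(material, float(row.hu), sd))
    return out


def write_table(table: CalibrationTable, path: PathLike, decimals: int = 1) -> None:
    """Write ``hu,value`` CSV with a ``# kind:`` header; HU rounded for export."""
    lines = [f"# kind: {table.kind}", "hu,value"]
    for p in table.points:
        lines.append(f"{round(p.hu, decimals)},{p.value:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(path: PathLike, provenance: str = "rtps_registered") -> CalibrationTable:
    """Read a calibration-table CSV written by :func:`write_table` (or an
    RTPS export in the same format)."""
    path = Path(path)
    kind = None
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#") and "kind:" in first:
        kind = first.split("kind:")[1].strip().upper()
    if kind not in ("MD", "RED"):
        raise ValueError(f"{path}: missing or invalid '# kind: MD|RED' header")
    df = pd.read_csv(path, comment="#")
    points = tuple(
        CalibrationPoint(float(h), float(v))
        for h, v in sorted(zip(df["hu"], df["value"]))
    )
    return CalibrationTable(kind, points, provenance=provenance)


def write_image_csv(pixels: np.ndarray, path: PathLike) -> None:
    np.savetxt(path, np.asarray(pixels, dtype=float), delimiter=",", fmt="%.4f")


def read_image_csv(path: PathLike) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def read_dicom_image(path: PathLike) -> tuple[np.ndarray, float]:
    """Read a single-frame DICOM CT slice; returns (HU pixels, spacing mm).

    Rescale slope and intercept are applied to map stored values to HU.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = ds.pixel_array.astype(float) * slope + intercept
    spacing = float(ds.PixelSpacing[0]) if hasattr(ds, "PixelSpacing") else 1.0
    return pixels, spacing


def fit_report_dict(fit: FitResult) -> dict:
    d = {
        "model": fit.model,
        "params": {"k1": fit.params.k1, "k2": fit.params.k2},
        "ssr": fit.ssr,
        "n_materials": fit.n_materials,
        "n_elements": fit.n_elements,
        "identifiable": fit.identifiable,
        "residuals": {
            name: float(r)
            for name, r in zip(fit.material_names, fit.residuals)
        },
    }
    if fit.params.alpha is not None:
        d["params"]["alpha"] = fit.params.alpha
    return d


def write_fit_report(fit: FitResult, path: PathLike) -> None:
    Path(path).write_text(json.dumps(fit_report_dict(fit), indent=2) + "\n")


def read_fit_report(path: PathLike) -> AttenuationParams:
    d = json.loads(Path(path).read_text())
    p = d["params"]
    return AttenuationParams(p["k1"], p["k2"], p.get("alpha"))
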
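"""CT-to-mass-density and CT-to-electron-density calibration tables.

Given fitted attenuation parameters, each of the eleven representative
tissues contributes one breakpoint: its theoretical CT number paired with
its mass density (CT-MD table) or its relative electron density (CT-RED
table).  Tables evaluate by piecewise-linear interpolation, clamped to the
end values outside the covered HU range — the segment-table convention of
commercial treatment planning systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .datasets import REPRESENTATIVE_TISSUE_DATA, _pct
from .materials import MaterialComposition, relative_electron_density
from .model import AttenuationParams, theoretical_hu

__all__ = [
    "RepresentativeTissue",
    "CalibrationPoint",
    "CalibrationTable",
    "representative_tissues",
    "build_tables",
    "evaluate",
    "table_red_consistency",
]

# Breakpoints closer than this in HU are collapsed to their mean value.
_HU_DUPLICATE_TOL = 0.5


@dataclass(frozen=True)
class RepresentativeTissue:
    """A standard human tissue with composition and published RED."""

    name: str
    composition: MaterialComposition
    red: float

    def __post_init__(self) -> None:
        if self.red <= 0:
            raise ValueError(f"{self.name}: RED must be positive")


def representative_tissues() -> list[RepresentativeTissue]:
    """The eleven bundled ICRP-110-derived representative tissues."""
    out = []
    for name, rho, red, weights, residual in REPRESENTATIVE_TISSUE_DATA:
        out.append(
            RepresentativeTissue(name, _pct(name, rho, weights, residual), red)
        )
    return out


@dataclass(frozen=True)
class CalibrationPoint:
    hu: float
    value: float  # MD in g/cm^3 or RED (dimensionless)


@dataclass(frozen=True)
class CalibrationTable:
    """Ordered (HU -> MD) or (HU -> RED) breakpoints."""

    kind: str  # "MD" | "RED"
    points: tuple[CalibrationPoint, ...]
    provenance: str = "stoichiometric"  # | "rtps_registered"

    def __post_init__(self) -> None:
        if self.kind not in ("MD", "RED"):
            raise ValueError(f"table kind must be MD or RED, got {self.kind!r}")
        if len(self.points) < 2:
            raise ValueError("a calibration table needs at least 2 points")
        hu = [p.hu for p in self.points]
        if any(b <= a for a, b in zip(hu, hu[1:])):
            raise ValueError("breakpoints must be strictly increasing in HU")
        if any(p.value < 0 for p in self.points):
            raise ValueError("table values must be non-negative")
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def hu_values(self) -> np.ndarray:
        return np.array([p.hu for p in self.points])

    @property
    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.points])


def _collapse_duplicates(
    pairs: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    pairs = sorted(pairs)
    merged: list[list[float]] = []
    for hu, val in pairs:
        if merged and hu - merged[-1][0] < _HU_DUPLICATE_TOL:
            # running mean of both coordinates within the cluster
            n = merged[-1][2] + 1
            merged[-1][0] += (hu - merged[-1][0]) / n
            merged[-1][1] += (val - merged[-1][1]) / n
            merged[-1][2] = n
        else:
            merged.append([hu, val, 1])
    return [(m[0], m[1]) for m in merged]


def build_tables(
    p: AttenuationParams,
    tissues: Optional[Sequence[RepresentativeTissue]] = None,
) -> tuple[CalibrationTable, CalibrationTable]:
    """Build the (CT-MD, CT-RED) table pair from fitted parameters.

    Each tissue contributes its theoretical CT number paired with its mass
    density and its RED.  Output is sorted by HU and invariant to tissue
    input order; near-coincident HU breakpoints (within 0.5 HU) are merged.
    A non-monotonic value ordering after the sort raises a warning but the
    table is still returned.
    """
    if tissues is None:
        tissues = representative_tissues()
    md_pairs, red_pairs = [], []
    for t in tissues:
        hu = theoretical_hu(t.composition, p)
        md_pairs.append((hu, t.composition.rho))
        red_pairs.append((hu, t.red))
    tables = []
    for kind, pairs in (("MD", md_pairs), ("RED", red_pairs)):
        pairs = _collapse_duplicates(pairs)
        vals = [v for _, v in pairs]
        if any(b < a for a, b in zip(vals, vals[1:])):
            warnings.warn(
                f"{kind} table values are not monotonic in HU", stacklevel=2
            )
        tables.append(
            CalibrationTable(kind, tuple(CalibrationPoint(h, v) for h, v in pairs))
        )
    return tables[0], tables[1]


def evaluate(table: CalibrationTable, hu: "float | np.ndarray"):
    """Piecewise-linear interpolation, clamped to end values outside the range."""
    result = np.interp(hu, table.hu_values, table.values)
    return float(result) if np.isscalar(hu) else result


def table_red_consistency(
    tissues: Optional[Iterable[RepresentativeTissue]] = None,
) -> list[dict]:
    """Compare each tissue's published RED with the value recomputed from
    its composition; returns one record per tissue with the absolute gap."""
    if tissues is None:
        tissues = representative_tissues()
    report = []
    for t in tissues:
        recomputed = relative_electron_density(t.composition)
        report.append(
            {
                "name": t.name,
                "red_published": t.red,
                "red_recomputed": recomputed,
                "abs_difference": abs(t.red - recomputed),
            }
        )
    return report
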
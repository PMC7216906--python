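"""Audit of a registered CT calibration table against a stoichiometric one.

The difference curve, audit-table value minus RTPS-table value, is sampled
on a grid over the tables' common HU span.  Samples are assigned to
tissue-type mass-density bands — lung, adipose/muscle, and
cartilage/spongy-bone — and per-band difference statistics are compared to
tolerance levels derived from a stated dose-calculation error (2 % by
default, or a stricter 1.4 % set).  Membership in a band is decided by the
mass density the audit calibration assigns to each grid HU; for RED audits
a companion CT-MD table from the same fit supplies that density.

A calibration error is declared when the mean band difference exceeds the
tolerance level; samples beyond the level with an in-tolerance mean are
reported as an exceedance rate but do not fail the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .tissues import CalibrationTable, evaluate

__all__ = [
    "ToleranceSpec",
    "BandDifferenceSummary",
    "AuditReport",
    "tolerance_set",
    "scaled_level",
    "difference_curve",
    "band_summary",
    "water_check",
    "run_audit",
    "WATER_HU_TOLERANCE",
]

# Water CT number must lie within 0 +/- 5 HU.
WATER_HU_TOLERANCE = 5.0

# Tolerance levels for a 2 % dose-calculation error under an effective-depth
# inhomogeneity correction, per tissue-type mass-density band.
_BASE_LEVELS_2PCT = {"lung": 0.044, "adipose_muscle": 0.022,
                     "cartilage_spongy_bone": 0.044}


@dataclass(frozen=True)
class ToleranceSpec:
    """A mass-density band [low, high) with its allowed |difference|."""

    name: str
    md_range: tuple[float, float]
    level: float

    def __post_init__(self) -> None:
        low, high = self.md_range
        if not (0 <= low < high):
            raise ValueError(f"{self.name}: invalid MD range {self.md_range}")
        if self.level <= 0:
            raise ValueError(f"{self.name}: tolerance level must be positive")

    def contains(self, md: float) -> bool:
        return self.md_range[0] <= md < self.md_range[1]


def scaled_level(base_level: float, dose_error_pct: float) -> float:
    """Rescale a 2 %-dose tolerance level to another dose error, rounded to
    3 decimals (tolerance ~ dose error under the effective-depth model)."""
    return round(base_level * dose_error_pct / 2.0, 3)


def tolerance_set(
    dose_error_pct: float = 2.0, adipose_low: float = 0.9
) -> list[ToleranceSpec]:
    """Standard band set for a given dose-error budget.

    ``dose_error_pct=2.0`` gives levels 0.044 / 0.022 / 0.044;
    ``dose_error_pct=1.4`` gives the stricter 0.031 / 0.015 / 0.031.
    ``adipose_low`` may be raised to 0.95 to exclude the sparsely
    populated 0.90-0.95 g/cm^3 fat margin.
    """
    if adipose_low not in (0.9, 0.95):
        raise ValueError("adipose_low must be 0.9 or 0.95")
    ranges = {
        "lung": (0.2, 0.8),
        "adipose_muscle": (adipose_low, 1.07),
        "cartilage_spongy_bone": (1.07, 1.25),
    }
    return [
        ToleranceSpec(name, ranges[name],
                      scaled_level(base, dose_error_pct))
        for name, base in _BASE_LEVELS_2PCT.items()
    ]


@dataclass(frozen=True)
class BandDifferenceSummary:
    """Difference statistics and tolerance verdict for one MD band."""

    name: str
    level: float
    differences: np.ndarray
    verdict: str = field(init=False)  # pass | investigate | fail | not-evaluable

    def __post_init__(self) -> None:
        d = np.asarray(self.differences, dtype=float)
        object.__setattr__(self, "differences", d)
        if d.size == 0:
            verdict = "not-evaluable"
        elif abs(self.mean) > self.level:
            verdict = "fail"
        elif self.exceed_rate > 0:
            verdict = "investigate"
        else:
            verdict = "pass"
        object.__setattr__(self, "verdict", verdict)

    @property
    def count(self) -> int:
        return int(self.differences.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.differences)) if self.count else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.differences, ddof=1)) if self.count > 1 else 0.0

    @property
    def exceed_rate(self) -> float:
        if not self.count:
            return 0.0
        return float(np.mean(np.abs(self.differences) > self.level))

    def to_dict(self) -> dict:
        return {
            "band": self.name,
            "level": self.level,
            "count": self.count,
            "mean": self.mean if self.count else None,
            "sd": self.sd if self.count else None,
            "exceed_rate": self.exceed_rate,
            "verdict": self.verdict,
        }


@dataclass(frozen=True)
class AuditReport:
    """Water check, per-band verdicts, and metadata for one audited table."""

    kind: str  # MD | RED
    water_hu: Optional[float]
    band_summaries: tuple[BandDifferenceSummary, ...]
    metadata: dict = field(default_factory=dict)

    @property
    def water_verdict(self) -> Optional[str]:
        if self.water_hu is None:
            return None
        return water_check(self.water_hu)

    @property
    def overall_pass(self) -> bool:
        bands_ok = all(b.verdict != "fail" for b in self.band_summaries)
        water_ok = self.water_verdict in (None, "pass")
        return bands_ok and water_ok

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "water_hu": self.water_hu,
            "water_verdict": self.water_verdict,
            "bands": [b.to_dict() for b in self.band_summaries],
            "overall_pass": self.overall_pass,
            "metadata": self.metadata,
        }


def difference_curve(
    audit: CalibrationTable,
    rtps: CalibrationTable,
    grid: Optional[np.ndarray] = None,
    step: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled (audit - RTPS) difference over the tables' HU range.

    The default grid is the union of both tables' breakpoints plus uniform
    ``step``-HU samples over their common span; both curves are piecewise
    linear, so this grid resolves every kink.
    """
    if audit.kind != rtps.kind:
        raise ValueError(
            f"cannot compare a {audit.kind} table with a {rtps.kind} table"
        )
    if grid is None:
        lo = max(audit.hu_values.min(), rtps.hu_values.min())
        hi = min(audit.hu_values.max(), rtps.hu_values.max())
        grid = np.union1d(
            np.union1d(audit.hu_values, rtps.hu_values),
            np.arange(lo, hi, step),
        )
    grid = np.asarray(grid, dtype=float)
    diffs = evaluate(audit, grid) - evaluate(rtps, grid)
    return grid, diffs


def band_summary(
    grid: np.ndarray,
    diffs: np.ndarray,
    spec: ToleranceSpec,
    md_reference: CalibrationTable,
) -> BandDifferenceSummary:
    """Summarize the difference samples whose audit mass density falls in
    ``spec``'s band.  ``md_reference`` is the CT-MD table of the audit fit,
    used for band membership even when the differences are REDs."""
    if md_reference.kind != "MD":
        raise ValueError("band membership requires an MD reference table")
    md = evaluate(md_reference, np.asarray(grid, dtype=float))
    mask = (md >= spec.md_range[0]) & (md < spec.md_range[1])
    return BandDifferenceSummary(spec.name, spec.level, np.asarray(diffs)[mask])


def water_check(hu_mean: float) -> str:
    """Verdict on a measured water CT number: pass iff |H| <= 5 HU."""
    return "pass" if abs(hu_mean) <= WATER_HU_TOLERANCE else "fail"


def run_audit(
    audit: CalibrationTable,
    rtps: CalibrationTable,
    md_reference: CalibrationTable,
    tolerances: Optional[Sequence[ToleranceSpec]] = None,
    water_hu: Optional[float] = None,
    step: float = 10.0,
    metadata: Optional[dict] = None,
) -> AuditReport:
    """Full audit: difference curve, band summaries, and water check."""
    if tolerances is None:
        tolerances = tolerance_set()
    grid, diffs = difference_curve(audit, rtps, step=step)
    summaries = tuple(
        band_summary(grid, diffs, spec, md_reference) for spec in tolerances
    )
    return AuditReport(
        kind=audit.kind,
        water_hu=water_hu,
        band_summaries=summaries,
        metadata=metadata or {},
    )
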